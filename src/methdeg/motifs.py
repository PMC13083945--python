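"""PWM motif scoring with methylation-sensitivity labels.

Motifs are position-probability matrices tagged MethylMinus (binding
impaired by CpG methylation), MethylPlus (binding enhanced) or unknown.
Each motif carries a derived log-odds detection threshold: positions whose
consensus-base probability exceeds 0.7 contribute ln(p/0.25) and the
threshold is the sum over positions.  Sequences are scanned on both strands
under the ZOOPS model (zero or one occurrence per sequence) and enrichment
of foreground hits over a background set is tested with the upper-tail
hypergeometric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
PROB_FLOOR = 1e-3


@dataclass
class MotifModel:
    """A position-probability matrix plus sensitivity label and threshold."""

    name: str
    matrix: np.ndarray                 # (L, 4), rows sum to 1
    label: str = "unknown"             # MethylMinus | MethylPlus | unknown
    threshold: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM must be L x 4")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("PWM probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        self.matrix = m
        if self.threshold is None:
            self.threshold = motif_threshold(m)

    def __len__(self) -> int:
        return len(self.matrix)


def motif_threshold(
    pwm: np.ndarray, base_p: float = 0.25, cutoff: float = 0.7,
    log=math.log,
) -> float:
    """Detection threshold: sum over positions of log(p_max/base_p) for
    positions whose maximum (consensus) base probability exceeds ``cutoff``;
    other positions contribute 0.  Natural log by default."""
    pmax = np.asarray(pwm, float).max(axis=1)
    return float(sum(log(p / base_p) for p in pmax if p > cutoff))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (incl. N) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)] = i
    return arr


def _logodds_columns(pwm: np.ndarray) -> np.ndarray:
    """(L, 5) log-odds ln(p/0.25) with probabilities floored at 1e-3 and a
    fifth column of zeros for N bases."""
    p = np.maximum(np.asarray(pwm, float), PROB_FLOOR)
    lo = np.log(p / 0.25)
    return np.column_stack([lo, np.zeros(len(p))])


def best_window_score(seq: str, motif: MotifModel) -> float:
    """Maximum log-odds window score over both strands; -inf if the sequence
    is shorter than the motif."""
    L = len(motif)
    best = -math.inf
    for strand_seq in (seq, reverse_complement(seq)):
        if len(strand_seq) < L:
            continue
        enc = _encode(strand_seq)
        lo = _logodds_columns(motif.matrix)
        n_win = len(enc) - L + 1
        # score all windows: gather per-position log-odds then sum
        scores = np.zeros(n_win)
        for j in range(L):
            scores += lo[j, enc[j:j + n_win]]
        best = max(best, float(scores.max()))
    return best


def scan_zoops(sequences: dict[str, str], motif: MotifModel) -> pd.Series:
    """ZOOPS hit call per sequence: True iff any window on either strand
    scores at or above the motif's detection threshold."""
    hits = {
        name: best_window_score(seq, motif) >= motif.threshold - 1e-9
        for name, seq in sequences.items()
    }
    return pd.Series(hits, name=motif.name)


def enrichment_test(
    fg_hits: dict[str, int | bool] | pd.DataFrame,
    bg_hits: dict[str, int | bool] | pd.DataFrame,
    motifs: list[MotifModel],
    n_fg: int | None = None,
    n_bg: int | None = None,
) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of foreground over background.

    ``fg_hits``/``bg_hits`` map motif name -> hit count (or a DataFrame of
    per-sequence booleans, columns = motifs).  The urn is the union of
    foreground and background sequences; p is the upper-tail probability of
    drawing at least the observed foreground hit count.
    """
    if isinstance(fg_hits, pd.DataFrame):
        n_fg = len(fg_hits)
        fg_hits = fg_hits.sum(axis=0).to_dict()
    if isinstance(bg_hits, pd.DataFrame):
        n_bg = len(bg_hits)
        bg_hits = bg_hits.sum(axis=0).to_dict()
    if n_fg is None or n_bg is None:
        raise ValueError("need foreground/background sequence totals")
    if n_bg < n_fg:
        import warnings

        warnings.warn("background smaller than foreground; enrichment p-values unstable")
    rows = []
    for m in motifs:
        k = int(fg_hits.get(m.name, 0))
        b = int(bg_hits.get(m.name, 0))
        K = k + b                              # hits in the urn
        p = stats.hypergeom.sf(k - 1, n_fg + n_bg, K, n_fg)
        fg_rate = k / n_fg if n_fg else np.nan
        bg_rate = b / n_bg if n_bg else np.nan
        fold = math.inf if (bg_rate == 0 and fg_rate > 0) else (
            fg_rate / bg_rate if bg_rate else np.nan
        )
        rows.append(
            {"motif": m.name, "label": m.label, "fg_hits": k, "fg_total": n_fg,
             "bg_hits": b, "bg_total": n_bg, "fold": fold, "p": float(p)}
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def read_pwm(path) -> MotifModel:
    """Read a tab-separated PPM file: header line ``name<TAB>label`` then
    one row of 4 probabilities per motif position."""
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    name = header[0]
    label = header[1] if len(header) > 1 else "unknown"
    matrix = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:]])
    return MotifModel(name=name, matrix=matrix, label=label)


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                sequences[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences
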