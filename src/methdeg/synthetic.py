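"""Synthetic genomes, methylomes, transcriptomes and annotation fixtures.

Everything downstream of raw data — site filtering, smoothed-t DMR calling,
enrichment, motif scanning, differential expression and methylation-
expression integration — is exercised on data generated here, with planted
effects whose ground truth is known:

* a genome layout with geometric inter-CpG spacing and simple gene models;
* per-sample CpG counts: totals Poisson, methylated counts beta-binomial
  around a per-CpG baseline, shifted by +-delta inside planted regions for
  the disease group (mild donors draw a per-donor shift from
  {0, delta/2, delta} to emulate mixed early-disease profiles);
* negative-binomial expression counts whose per-donor means are monotonically
  tied (log-linearly) to the methylation of an assigned region;
* chromatin-state tilings, enhancer-gene link tables, PWM motif sets and
  region sequences with consensus sites planted at a configurable rate.

A single integer seed makes every output bit-identical across runs;
per-sample RNG streams are derived deterministically from it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MethylationCallSet

STATE_NAMES = [
    "TssA", "TssAFlnk", "Tx", "EnhG", "Enh", "ReprPC", "Quies",
]

BASES = np.array(list("ACGT"))


@dataclass
class GenomeLayout:
    """Chromosome sizes plus sorted 0-based CpG positions per chromosome."""

    chromosomes: list[tuple[str, int]]
    cpg_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, pos in self.cpg_positions.items():
            pos = np.asarray(pos)
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"{chrom}: CpG positions not strictly increasing")
            if len(pos) and pos[-1] >= lengths[chrom]:
                raise ValueError(f"{chrom}: CpG position beyond chromosome end")
            self.cpg_positions[chrom] = pos

    @property
    def n_cpg(self) -> int:
        return sum(len(p) for p in self.cpg_positions.values())


@dataclass
class StudyDesign:
    """Sample sheet: (sample_id, group) with group in {control, mild, severe}."""

    samples: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        bad = {g for _, g in self.samples} - {"control", "mild", "severe"}
        if bad:
            raise ValueError(f"unknown groups: {bad}")

    @classmethod
    def default(cls, n_control: int = 3, n_mild: int = 3, n_severe: int = 5):
        samples = (
            [(f"ctrl{i+1}", "control") for i in range(n_control)]
            + [(f"mild{i+1}", "mild") for i in range(n_mild)]
            + [(f"sev{i+1}", "severe") for i in range(n_severe)]
        )
        return cls(samples)

    def ids(self, group: str | None = None) -> list[str]:
        return [s for s, g in self.samples if group is None or g == group]

    @property
    def groups(self) -> dict:
        return dict(self.samples)


@dataclass
class PlantedEffect:
    """A region with a planted group methylation difference, optionally tied
    to a gene's expression with a signed monotone link."""

    chrom: str
    start: int
    end: int
    direction: str                       # hyper | hypo (severe vs control)
    delta: float                         # group methylation difference in [0,1]
    baseline_mu: float = 0.5             # control-group mean methylation
    linked_gene: str | None = None
    link_sign: str = "none"              # negative | positive | none

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.direction not in {"hyper", "hypo"}:
            raise ValueError("direction must be hyper or hypo")
        if self.direction == "hyper" and self.baseline_mu + self.delta > 1 + 1e-9:
            raise ValueError("hyper effect exceeds methylation 1")
        if self.direction == "hypo" and self.baseline_mu - self.delta < -1e-9:
            raise ValueError("hypo effect below methylation 0")

    @property
    def signed_delta(self) -> float:
        return self.delta if self.direction == "hyper" else -self.delta


def _stable_hash(x) -> int:
    digest = hashlib.blake2b(repr(x).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def _rng(seed: int, *stream) -> np.random.Generator:
    """Deterministic sub-stream RNG: stable across processes (no reliance on
    Python's randomized string hashing)."""
    return np.random.default_rng([int(seed)] + [_stable_hash(x) for x in stream])


def simulate_genome(
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    mean_cpg_spacing: int = 100,
    n_genes_per_chrom: int = 40,
    seed: int = 0,
):
    """Draw a genome layout (geometric inter-CpG gaps) and simple gene models.

    Returns ``(GenomeLayout, genes)`` where genes is a DataFrame with columns
    gene_id, chrom, strand, start, end, biotype, exons (list of 0-based
    half-open intervals).  TSSs are unique; both strands are represented.
    """
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    if chrom_length < 1:
        raise ValueError("chromosome length must be positive")
    if mean_cpg_spacing < 2:
        raise ValueError("mean_cpg_spacing must be >= 2 bp")

    rng = np.random.default_rng(seed)
    chromosomes, cpg_positions = [], {}
    gene_rows = []
    gene_counter = 0
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        chromosomes.append((name, chrom_length))
        n_draw = int(2 * chrom_length / mean_cpg_spacing) + 100
        gaps = rng.geometric(1.0 / mean_cpg_spacing, size=n_draw)
        pos = np.cumsum(gaps) - 1
        cpg_positions[name] = pos[pos < chrom_length].astype(np.int64)

        # genes on a jittered lattice so TSSs are unique and well spread
        pitch = chrom_length // max(n_genes_per_chrom, 1)
        for g in range(n_genes_per_chrom):
            gene_counter += 1
            anchor = g * pitch + int(rng.integers(0, max(pitch // 4, 1)))
            length = int(rng.integers(2_000, 20_000))
            start = min(anchor, chrom_length - length - 1)
            end = start + length
            strand = "+" if (gene_counter % 2 == 1) else "-"
            n_exon = int(rng.integers(1, 4))
            cuts = np.sort(rng.integers(0, length, size=2 * n_exon))
            exons = [
                (start + int(cuts[2 * i]), start + int(cuts[2 * i + 1]) + 1)
                for i in range(n_exon)
            ]
            biotype = rng.choice(
                ["protein_coding", "lncRNA", "other"], p=[0.8, 0.15, 0.05]
            )
            gene_rows.append(
                {
                    "gene_id": f"G{gene_counter:04d}",
                    "chrom": name,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "biotype": str(biotype),
                    "exons": exons,
                }
            )
    genes = pd.DataFrame(gene_rows)
    return GenomeLayout(chromosomes, cpg_positions), genes


def _baseline_mu(layout: GenomeLayout, seed: int) -> dict[str, np.ndarray]:
    """Per-CpG baseline methylation: bimodal, mostly-high landscape shared by
    all samples (CpG-island-like lows, methylated-body highs)."""
    out = {}
    for chrom, pos in layout.cpg_positions.items():
        r = _rng(seed, "baseline", chrom)
        low = r.random(len(pos)) < 0.25
        mu = np.where(low, r.beta(2, 8, len(pos)), r.beta(8, 2, len(pos)))
        out[chrom] = np.clip(mu, 0.02, 0.98)
    return out


def _check_effects(effects: list[PlantedEffect]) -> None:
    by_chrom: dict[str, list[PlantedEffect]] = {}
    for e in effects:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end and a.direction != b.direction:
                raise ValueError(
                    f"overlapping planted effects with conflicting direction on {chrom}"
                )


def simulate_methylation(
    layout: GenomeLayout,
    design: StudyDesign,
    effects: list[PlantedEffect],
    coverage_mean: float = 10.0,
    dispersion: float = 30.0,
    mild_shift_choices=(0.0, 0.5, 1.0),
    seed: int = 0,
) -> dict[str, MethylationCallSet]:
    """Beta-binomial methylation counts per sample.

    Total counts are Poisson(coverage_mean); methylated counts are
    beta-binomial with precision ``dispersion`` around the sample-level mean:
    the shared baseline, shifted by the full signed delta for severe donors
    and by a per-donor fraction of it (drawn from ``mild_shift_choices``)
    for mild donors, inside each planted region.
    """
    if coverage_mean < 1:
        raise ValueError("coverage_mean must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion (beta-binomial precision) must be > 0")
    _check_effects(effects)

    baseline = _baseline_mu(layout, seed)

    # per-donor shift multiplier: severe 1, control 0, mild drawn once
    multipliers = {}
    for sample_id, group in design.samples:
        if group == "severe":
            multipliers[sample_id] = 1.0
        elif group == "control":
            multipliers[sample_id] = 0.0
        else:
            r = _rng(seed, "mildshift", sample_id)
            multipliers[sample_id] = float(r.choice(mild_shift_choices))

    callsets = {}
    for sample_id, group in design.samples:
        frames = []
        for chrom, pos in layout.cpg_positions.items():
            mu = baseline[chrom].copy()
            for e in effects:
                if e.chrom != chrom:
                    continue
                inside = (pos >= e.start) & (pos < e.end)
                shifted = e.baseline_mu + multipliers[sample_id] * e.signed_delta
                mu[inside] = np.clip(shifted, 0.01, 0.99)
            r = _rng(seed, "meth", sample_id, chrom)
            n = r.poisson(coverage_mean, size=len(pos))
            p = r.beta(mu * dispersion, (1 - mu) * dispersion)
            m = r.binomial(n, p)
            frames.append(
                pd.DataFrame({"chrom": chrom, "pos": pos, "m": m, "n": n})
            )
        data = pd.concat(frames, ignore_index=True)
        callsets[sample_id] = MethylationCallSet(sample_id, data[data["n"] > 0])
    return callsets


def region_mean_beta(
    callsets: dict[str, MethylationCallSet], chrom: str, start: int, end: int
) -> dict[str, float]:
    """Per-donor unweighted mean beta over CpGs inside [start, end)."""
    out = {}
    for sample_id, cs in callsets.items():
        d = cs.data
        inside = (d["chrom"] == chrom) & (d["pos"] >= start) & (d["pos"] < end)
        sub = d[inside]
        n = sub["n"].to_numpy(float)
        betas = sub["m"].to_numpy(float)[n > 0] / n[n > 0]
        out[sample_id] = float(betas.mean()) if len(betas) else np.nan
    return out


def simulate_expression(
    genes: pd.DataFrame,
    callsets: dict[str, MethylationCallSet],
    effects: list[PlantedEffect],
    nb_dispersion: float = 0.05,
    slope: float = 8.0,
    baseline_log2_range=(4.0, 10.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x sample NB counts with methylation-linked means.

    For a gene linked (via a planted effect) to a region, the per-donor log2
    mean is ``baseline + s * region_mean_beta`` with s = -slope for negative
    links and +slope for positive ones; unlinked genes have flat means.
    Counts are NB with dispersion ``nb_dispersion`` (var = mu + disp*mu^2).
    """
    links = {e.linked_gene: e for e in effects if e.linked_gene is not None}
    missing = set(links) - set(genes["gene_id"])
    if missing:
        raise ValueError(f"linked genes absent from gene models: {sorted(missing)}")

    samples = list(callsets)
    rng = _rng(seed, "expr")
    base = rng.uniform(*baseline_log2_range, size=len(genes))

    region_beta = {
        g: region_mean_beta(callsets, e.chrom, e.start, e.end)
        for g, e in links.items()
    }

    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    size = 1.0 / nb_dispersion
    for i, gene_id in enumerate(genes["gene_id"]):
        log2mu = np.full(len(samples), base[i])
        if gene_id in links:
            e = links[gene_id]
            s = -slope if e.link_sign == "negative" else (
                slope if e.link_sign == "positive" else 0.0
            )
            bet = np.array([region_beta[gene_id][smp] for smp in samples])
            # centre the link on 0.5 so baseline stays the typical level
            log2mu = base[i] + s * (np.nan_to_num(bet, nan=0.5) - 0.5)
        mu = np.power(2.0, log2mu)
        r = _rng(seed, "exprgene", gene_id)
        counts[i] = r.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(counts, index=list(genes["gene_id"]), columns=samples)


def simulate_sequence(
    layout: GenomeLayout, gc: float = 0.42, seed: int = 0
) -> dict[str, str]:
    """IID random genome sequence at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for chrom, length in layout.chromosomes:
        r = _rng(seed, "seq", chrom)
        out[chrom] = "".join(BASES[r.choice(4, size=length, p=p)])
    return out


def simulate_annotations(
    layout: GenomeLayout,
    effects: list[PlantedEffect],
    seed: int = 0,
    mean_state_length: int = 20_000,
    region_length: int = 500,
    n_background_regions: int = 50,
    planting_rate: float = 1.0,
    consensus: str = "GGAAGTGGAA",
):
    """Fixture annotations: a chromatin-state tiling, an enhancer-gene link
    table, a small PWM set and region sequences with the designated motif's
    consensus planted in hypo-region sequences at ``planting_rate``.

    Returns a dict with keys ``states`` (BED-like DataFrame), ``enhancers``
    (DataFrame), ``motifs`` (list of (name, label, matrix)), ``sequences``
    (dict name -> sequence) and ``foreground_names`` / ``background_names``.
    """
    rng = _rng(seed, "annot")

    # chromatin states tile each chromosome exactly: no gaps, no overlaps
    state_rows = []
    for chrom, length in layout.chromosomes:
        pos = 0
        while pos < length:
            seg = int(rng.integers(mean_state_length // 2, mean_state_length * 2))
            end = min(pos + seg, length)
            state_rows.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": end,
                    "state": str(rng.choice(STATE_NAMES)),
                }
            )
            pos = end
    states = pd.DataFrame(state_rows)

    # enhancer-gene association table over the planted effect regions
    enh_rows = []
    for i, e in enumerate(effects):
        if e.linked_gene is None:
            continue
        enh_rows.append(
            {
                "element_id": f"GH{i:04d}",
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "gene_id": e.linked_gene,
                "biotype": "protein_coding",
                "score": float(np.round(rng.uniform(5, 25), 2)),
                "elite": bool(rng.random() < 0.7),
            }
        )
    enhancers = pd.DataFrame(
        enh_rows,
        columns=["element_id", "chrom", "start", "end", "gene_id",
                 "biotype", "score", "elite"],
    )

    # a sharp planted motif plus a soft decoy
    planted = _consensus_ppm(consensus, sharpness=0.95)
    decoy = _consensus_ppm("TTTTCACTTT", sharpness=0.6)
    motifs = [
        ("PLANTED", "MethylMinus", planted),
        ("DECOY", "unknown", decoy),
    ]

    sequences: dict[str, str] = {}
    fg_names, bg_names = [], []
    for i, e in enumerate(effects):
        name = f"region_{e.direction}_{i}"
        r = _rng(seed, "regionseq", name)
        seq = "".join(BASES[r.integers(0, 4, size=region_length)])
        if e.direction == "hypo" and r.random() < planting_rate:
            ins = int(r.integers(0, region_length - len(consensus)))
            seq = seq[:ins] + consensus + seq[ins + len(consensus):]
        sequences[name] = seq
        fg_names.append(name)
    for i in range(n_background_regions):
        name = f"bg_{i}"
        r = _rng(seed, "bgseq", name)
        sequences[name] = "".join(BASES[r.integers(0, 4, size=region_length)])
        bg_names.append(name)

    return {
        "states": states,
        "enhancers": enhancers,
        "motifs": motifs,
        "sequences": sequences,
        "foreground_names": fg_names,
        "background_names": bg_names,
    }


def _consensus_ppm(consensus: str, sharpness: float = 0.95) -> np.ndarray:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(consensus)
    ppm = np.full((L, 4), (1 - sharpness) / 3)
    for i, b in enumerate(consensus):
        ppm[i, idx[b]] = sharpness
    return ppm


def plant_effects_evenly(
    layout: GenomeLayout,
    n_effects: int,
    n_cpg_per_effect: int = 10,
    delta: float = 0.3,
    baseline_mu: float = 0.6,
    directions=("hypo", "hyper"),
    genes: pd.DataFrame | None = None,
    link_sign: str = "none",
    max_internal_gap: int | None = 300,
    seed: int = 0,
) -> list[PlantedEffect]:
    """Spread n_effects regions of n_cpg_per_effect consecutive CpGs evenly
    across the genome (well separated, so stitching cannot merge them),
    alternating directions, optionally linking each to a distinct gene.

    Planted windows are chosen at locally CpG-dense sites: every internal
    inter-CpG gap is <= max_internal_gap, mirroring real DMRs, which sit at
    CpG clusters, and keeping the ground truth consistent with the region
    definition (>= 3 CpGs within 300 bp).  Set max_internal_gap=None to
    plant at arbitrary spacing.
    """
    all_cpgs = [
        (chrom, i) for chrom, pos in layout.cpg_positions.items()
        for i in range(len(pos))
    ]
    total = len(all_cpgs)
    stride = total // (n_effects + 1)
    effects = []
    used_genes: set = set()
    for k in range(n_effects):
        chrom, i0 = all_cpgs[(k + 1) * stride]
        pos = layout.cpg_positions[chrom]
        if max_internal_gap is not None:
            i0 = _first_dense_window(pos, i0, n_cpg_per_effect, max_internal_gap)
        i1 = min(i0 + n_cpg_per_effect, len(pos)) - 1
        direction = directions[k % len(directions)]
        linked = None
        if link_sign != "none" and genes is not None:
            # tie each effect to the nearest-TSS gene so promoter-proximal
            # assignment can recover the planted pair; prefer unused genes
            mid = (int(pos[i0]) + int(pos[i1])) // 2
            linked = _nearest_gene(genes, chrom, mid, used_genes)
            if linked is not None:
                used_genes.add(linked)
        effects.append(
            PlantedEffect(
                chrom=chrom,
                start=int(pos[i0]),
                end=int(pos[i1]) + 2,    # include the CG dinucleotide
                direction=direction,
                delta=delta,
                baseline_mu=baseline_mu,
                linked_gene=linked,
                link_sign=link_sign if linked else "none",
            )
        )
    return effects


def _nearest_gene(genes: pd.DataFrame, chrom: str, midpoint: int,
                  exclude: set) -> str | None:
    on = genes[genes["chrom"] == chrom]
    if on.empty:
        return None
    tss = np.where(on["strand"].to_numpy() == "+",
                   on["start"].to_numpy(), on["end"].to_numpy() - 1)
    order = np.argsort(np.abs(tss - midpoint), kind="stable")
    ids = on["gene_id"].to_numpy()[order]
    for gid in ids:
        if gid not in exclude:
            return str(gid)
    return str(ids[0])


def _first_dense_window(pos: np.ndarray, i0: int, n_cpg: int, max_gap: int) -> int:
    """First index >= i0 whose window of n_cpg consecutive CpGs has every
    internal gap <= max_gap (falls back to i0 if none exists)."""
    gaps = np.diff(pos)
    for i in range(i0, len(pos) - n_cpg):
        if (gaps[i:i + n_cpg - 1] <= max_gap).all():
            return i
    return i0


# ---------------------------------------------------------------- writers

def write_bed(df: pd.DataFrame, path, cols=("chrom", "start", "end")) -> None:
    extra = [c for c in df.columns if c not in cols]
    df[list(cols) + extra].to_csv(path, sep="\t", header=False, index=False)


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_pwm(name: str, label: str, matrix: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{name}\t{label}\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def write_metadata(design: StudyDesign, path) -> None:
    pd.DataFrame(design.samples, columns=["sample_id", "group"]).to_csv(
        path, sep="\t", index=False
    )
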