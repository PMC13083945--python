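"""Reading CpG-level methylation calls and genome-wide QC summaries.

The substrate of the whole pipeline is a per-sample table of methylated /
total read counts at CpG positions.  Counts arrive in the bismark-coverage
dialect (1-based, percentage + methylated + unmethylated columns) or as a
4-column bedGraph carrying beta values only.  All internal coordinates are
0-based half-open; readers convert on the way in, writers on the way out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class MethylationCallSet:
    """Per-sample methylated (m) / total (n) read counts at CpG coordinates.

    ``data`` has columns ``chrom, pos, m, n`` with ``pos`` 0-based, unique and
    sorted within each chromosome, ``0 <= m <= n``.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "m", "n"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"call set missing columns: {missing}")
        d = self.data
        if len(d) and ((d["m"] < 0).any() or (d["m"] > d["n"]).any()):
            raise ValueError("require 0 <= m <= n at every CpG")
        self.data = (
            d.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        )
        dup = self.data.duplicated(["chrom", "pos"])
        if dup.any():
            raise ValueError(
                f"duplicate CpG coordinates in sample {self.sample_id!r}"
            )

    @property
    def beta(self) -> np.ndarray:
        """Methylation fraction m/n; NaN where n == 0."""
        n = self.data["n"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.data["m"].to_numpy(float) / n, np.nan)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FilteredMatrix:
    """CpG x sample matrix of beta values and coverage after site filtering.

    Every retained CpG has coverage >= ``min_cov`` in all samples and lies on
    a retained chromosome; provenance records the filter parameters applied.
    """

    index: pd.DataFrame            # columns chrom, pos (0-based)
    beta: np.ndarray               # (n_cpg, n_samples)
    cov: np.ndarray                # (n_cpg, n_samples) total counts
    samples: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta.shape != self.cov.shape:
            raise ValueError("beta and coverage shapes differ")
        if self.beta.shape != (len(self.index), len(self.samples)):
            raise ValueError("matrix shape does not match index/samples")

    @property
    def n_cpg(self) -> int:
        return len(self.index)

    def sample_columns(self, sample_ids) -> np.ndarray:
        idx = [self.samples.index(s) for s in sample_ids]
        return self.beta[:, idx]

    def subset(self, mask: np.ndarray) -> "FilteredMatrix":
        return FilteredMatrix(
            self.index.loc[mask].reset_index(drop=True),
            self.beta[mask],
            self.cov[mask],
            list(self.samples),
            dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.index.copy()
        for j, s in enumerate(self.samples):
            out[f"beta.{s}"] = self.beta[:, j]
            out[f"cov.{s}"] = self.cov[:, j]
        return out


def read_bismark_coverage(path, sample_id: str) -> MethylationCallSet:
    """Read a bismark-coverage TSV into a call set.

    Columns: chrom, start (1-based), end (1-based), methylation %,
    count-methylated, count-unmethylated.  Beta is recomputed from the two
    count columns; the percentage column is ignored.  Rows with zero total
    count are dropped (logged).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "pct", "m", "u"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "pct", "m", "u"])
    for col in ("start", "m", "u"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(
                f"{path}: malformed value in column {col!r} at line {bad.idxmax() + 1}"
            )
    neg = (df["m"] < 0) | (df["u"] < 0)
    if neg.any():
        raise ValueError(f"{path}: negative count at line {int(neg.idxmax()) + 1}")
    n = df["m"] + df["u"]
    dropped = int((n == 0).sum())
    if dropped:
        logger.info("%s: dropped %d zero-coverage rows", path, dropped)
    keep = df[n > 0]
    data = pd.DataFrame(
        {
            "chrom": keep["chrom"].astype(str),
            "pos": keep["start"].astype(int) - 1,   # to 0-based
            "m": keep["m"].astype(int),
            "n": (keep["m"] + keep["u"]).astype(int),
        }
    )
    return MethylationCallSet(sample_id, data)


def read_bedgraph(path, sample_id: str) -> MethylationCallSet:
    """Read a 4-column bedGraph of beta values (no counts).

    Coverage is unknown, so the returned call set carries n = 1 and
    m = beta pseudo-counts; coverage-based filters must be explicitly
    disabled when starting from bedGraph input.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "beta"], dtype={"chrom": str},
    )
    if ((df["beta"] < 0) | (df["beta"] > 1)).any():
        raise ValueError(f"{path}: beta outside [0, 1]")
    data = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(int),  # bedGraph is already 0-based
            "m": df["beta"].astype(float),
            "n": 1.0,
        }
    )
    return MethylationCallSet(sample_id, data)


def write_bismark_coverage(callset: MethylationCallSet, path) -> None:
    d = callset.data
    n = d["n"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n > 0, 100.0 * d["m"].to_numpy(float) / n, 0.0)
    out = pd.DataFrame(
        {
            "chrom": d["chrom"],
            "start": d["pos"] + 1,     # to 1-based
            "end": d["pos"] + 1,
            "pct": np.round(pct, 6),
            "m": d["m"].astype(int),
            "u": (d["n"] - d["m"]).astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_cpgs(
    callsets: list[MethylationCallSet],
    min_cov: int = 4,
    top_cov_fraction: float = 0.001,
    drop_chroms=SEX_CHROMOSOMES,
) -> FilteredMatrix:
    """Retain CpGs covered >= min_cov in every sample, trim ultra-high
    coverage sites, and drop excluded chromosomes.

    The top-coverage cut removes any CpG whose coverage lies in the top
    ``top_cov_fraction`` quantile of that sample's retained coverages, in any
    sample.  Filtering is idempotent for fixed parameters: passing an
    already-filtered matrix applies the absolute filters again (no-ops) and
    skips the quantile trim its provenance records as done, since that cut
    is defined relative to the pre-filter coverage distribution.
    """
    if isinstance(callsets, FilteredMatrix):
        return _refilter_matrix(callsets, min_cov, top_cov_fraction, drop_chroms)
    if not callsets:
        raise ValueError("need at least one call set")
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    drop_chroms = set(drop_chroms or ())

    samples = [cs.sample_id for cs in callsets]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")

    merged = None
    for cs in callsets:
        d = cs.data[~cs.data["chrom"].isin(drop_chroms)]
        d = d[d["n"] >= min_cov]
        part = d.set_index(["chrom", "pos"])[["m", "n"]]
        part.columns = pd.MultiIndex.from_product([[cs.sample_id], ["m", "n"]])
        merged = part if merged is None else merged.join(part, how="inner")
    merged = merged.sort_index()

    cov = np.column_stack([merged[(s, "n")].to_numpy(float) for s in samples])
    meth = np.column_stack([merged[(s, "m")].to_numpy(float) for s in samples])

    if top_cov_fraction > 0 and len(merged):
        # 'lower' interpolation so an isolated outlier above an otherwise flat
        # coverage distribution is always trimmed
        thr = np.quantile(cov, 1.0 - top_cov_fraction, axis=0, method="lower")
        keep = (cov <= thr).all(axis=1)
        cov, meth = cov[keep], meth[keep]
        merged = merged[keep]

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(cov > 0, meth / cov, np.nan)

    index = merged.index.to_frame(index=False)
    index.columns = ["chrom", "pos"]
    return FilteredMatrix(
        index=index,
        beta=beta,
        cov=cov,
        samples=samples,
        provenance={
            "min_cov": min_cov,
            "top_cov_fraction": top_cov_fraction,
            "drop_chroms": sorted(drop_chroms),
        },
    )


def _refilter_matrix(matrix: FilteredMatrix, min_cov, top_cov_fraction,
                     drop_chroms) -> FilteredMatrix:
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    drop_chroms = set(drop_chroms or ())
    keep = (
        (matrix.cov >= min_cov).all(axis=1)
        & ~matrix.index["chrom"].isin(drop_chroms).to_numpy()
    )
    if (
        top_cov_fraction > 0
        and matrix.provenance.get("top_cov_fraction") != top_cov_fraction
        and keep.any()
    ):
        thr = np.quantile(
            matrix.cov[keep], 1.0 - top_cov_fraction, axis=0, method="lower"
        )
        keep &= (matrix.cov <= thr).all(axis=1)
    out = matrix.subset(keep)
    out.provenance.update(
        {"min_cov": min_cov, "top_cov_fraction": top_cov_fraction,
         "drop_chroms": sorted(drop_chroms)}
    )
    return out


DECILE_EDGES = np.linspace(0.0, 1.0, 11)


def decile_frequency(matrix: FilteredMatrix, groups: dict) -> pd.DataFrame:
    """Per-group frequency of CpG methylation levels in 10 decile bins,
    with a per-bin Kruskal-Wallis test across groups on sample fractions.

    Bins are left-closed; the final bin [0.9, 1.0] is closed on both ends so
    fully methylated CpGs are counted.  Returns one row per bin with the
    group-mean fractions and the KW statistic / p-value.
    """
    if matrix.n_cpg == 0:
        raise ValueError("empty matrix")
    group_names = sorted(set(groups.values()))
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups")

    fracs = {}
    for j, s in enumerate(matrix.samples):
        counts, _ = np.histogram(matrix.beta[:, j], bins=DECILE_EDGES)
        fracs[s] = counts / counts.sum()

    rows = []
    for b in range(10):
        per_group = {
            g: [fracs[s][b] for s in matrix.samples if groups[s] == g]
            for g in group_names
        }
        vals = [np.asarray(v) for v in per_group.values()]
        flat = np.concatenate(vals)
        if np.allclose(flat, flat[0]):
            kw_stat, kw_p = 0.0, 1.0
        else:
            kw_stat, kw_p = stats.kruskal(*vals)
        row = {
            "bin_low": DECILE_EDGES[b],
            "bin_high": DECILE_EDGES[b + 1],
            "kw_stat": kw_stat,
            "kw_p": kw_p,
        }
        for g in group_names:
            row[f"freq.{g}"] = float(np.mean(per_group[g]))
        rows.append(row)
    return pd.DataFrame(rows)


def sample_decile_fractions(matrix: FilteredMatrix) -> pd.DataFrame:
    """Per-sample decile fractions (rows = bins, columns = samples)."""
    out = {}
    for j, s in enumerate(matrix.samples):
        counts, _ = np.histogram(matrix.beta[:, j], bins=DECILE_EDGES)
        out[s] = counts / counts.sum()
    return pd.DataFrame(out)


def pca_variable_cpgs(matrix: FilteredMatrix, n_top: int = 50_000):
    """PCA of the n_top most variable CpGs (variance of beta across samples).

    Betas are centred per CpG but not scaled.  Returns ``(scores,
    variance_fraction)`` where scores is (n_samples, n_components) and the
    variance fractions are non-increasing and sum to <= 1.
    """
    if len(matrix.samples) < 2:
        raise ValueError("PCA needs >= 2 samples")
    if n_top > matrix.n_cpg:
        raise ValueError("n_top exceeds number of CpGs")
    var = matrix.beta.var(axis=1)
    top = np.argsort(var, kind="stable")[::-1][:n_top]
    X = matrix.beta[np.sort(top)].T          # samples x CpGs
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    total_var = Xc.var(axis=0, ddof=1).sum()
    explained = (s ** 2) / (len(X) - 1)
    frac = explained / total_var if total_var > 0 else np.zeros_like(explained)
    return scores, frac
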