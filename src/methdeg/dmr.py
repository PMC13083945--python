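"""Smoothed-t differentially methylated region (DMR) calling.

The caller follows the BSmooth-style recipe: per-sample methylation is
locally smoothed along each chromosome, a between-group signal-to-noise
t-statistic is computed per CpG (severe minus control, pooled within-group
SD with a global variance floor), candidate regions are maximal runs of
CpGs in the 5% most extreme tail of the t distribution, candidates are
filtered for >= 10% raw methylation difference and >= 3 CpGs within 300 bp
of each other, a two-sided exact rank-sum test on per-sample region means
removes regions driven by non-normal tails, and same-direction regions
< 5 kb apart are stitched when the merged difference stays >= 10%.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FilteredMatrix

logger = logging.getLogger(__name__)


@dataclass
class SmoothedTrack:
    """Locally smoothed methylation estimates for every retained CpG."""

    matrix: FilteredMatrix
    smoothed: np.ndarray         # (n_cpg, n_samples), values in [0, 1]
    h: int
    min_cpgs_window: int


@dataclass
class TStatTrack:
    """Per-CpG group t-statistic (severe minus control) with group means."""

    matrix: FilteredMatrix
    t: np.ndarray
    mean_control: np.ndarray     # smoothed group means
    mean_severe: np.ndarray
    raw_delta: np.ndarray        # raw-beta group mean difference per CpG
    control_ids: list[str]
    severe_ids: list[str]
    sd_floor: float


@dataclass
class DMR:
    """A called region: coordinates are 0-based half-open."""

    id: str
    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_beta_control: float
    mean_beta_severe: float
    delta: float                  # mean(severe) - mean(control), raw betas
    direction: str                # hyper | hypo
    area: float                   # sum of t over member CpGs
    wilcoxon_p: float = math.nan
    passed_wilcoxon: bool = False
    stitched_from: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def _tricube(d: np.ndarray, span: float) -> np.ndarray:
    u = np.minimum(np.abs(d) / max(span, 1.0), 1.0)
    return (1.0 - u**3) ** 3


def smooth(matrix: FilteredMatrix, h: int = 1000, min_cpgs_window: int = 70) -> SmoothedTrack:
    """Local weighted binomial-proportion smoothing of each sample's track.

    For CpG i the window spans +-h bp, widened symmetrically (nearest CpG
    first) until it holds >= min_cpgs_window CpGs or the chromosome ends.
    A local-linear fit of beta against genomic distance, weighted by
    tricube(distance) times total read count, is evaluated at the CpG; the
    linear term removes the boundary bias a plain weighted mean shows at
    sharp methylation steps.  Estimates are clipped to [0, 1].  Chromosomes
    with fewer than 3 CpGs pass raw betas through with a warning.
    """
    beta, cov = matrix.beta, matrix.cov
    M = np.nan_to_num(beta) * cov
    out = np.empty_like(beta)

    chroms = matrix.index["chrom"].to_numpy()
    positions = matrix.index["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        p = positions[sel]
        n = len(sel)
        if n < 3:
            logger.warning("%s: <3 CpGs, smoothing skipped", chrom)
            out[sel] = np.nan_to_num(beta[sel])
            continue
        Mc, Nc = M[sel], cov[sel]
        Bc = np.nan_to_num(beta[sel])
        los = np.searchsorted(p, p - h, side="left")
        his = np.searchsorted(p, p + h, side="right")
        for i in range(n):
            lo, hi = int(los[i]), int(his[i])
            while hi - lo < min_cpgs_window and (lo > 0 or hi < n):
                dl = p[i] - p[lo - 1] if lo > 0 else np.inf
                dr = p[hi] - p[i] if hi < n else np.inf
                if dl <= dr:
                    lo -= 1
                else:
                    hi += 1
            d = (p[lo:hi] - p[i]).astype(float)
            span = max(abs(d[0]), abs(d[-1]), 1.0) + 1.0
            wt = _tricube(d, span)
            W = wt[:, None] * Nc[lo:hi]              # (k, n_samples)
            y = Bc[lo:hi]
            s0 = W.sum(axis=0)
            s1 = d @ W
            s2 = (d * d) @ W
            t0 = (W * y).sum(axis=0)
            t1 = (d[:, None] * W * y).sum(axis=0)
            det = s0 * s2 - s1 * s1
            with np.errstate(invalid="ignore", divide="ignore"):
                linear = (s2 * t0 - s1 * t1) / det
                mean = np.where(s0 > 0, t0 / s0, Bc[i])
            # fall back to the weighted mean where the design is degenerate
            ok = (det > 1e-9 * np.maximum(s0 * s2, 1e-300)) & np.isfinite(linear)
            out[sel[i]] = np.where(ok, linear, mean)
    return SmoothedTrack(matrix, np.clip(out, 0.0, 1.0), h, min_cpgs_window)


def group_tstat(
    track: SmoothedTrack,
    control_ids: list[str],
    severe_ids: list[str],
    sd_floor_quantile: float = 0.75,
    sd_floor: float | None = None,
) -> TStatTrack:
    """Per-CpG signal-to-noise t: (mean_severe - mean_control) / pooled SD,
    with the SD floored at the genome-wide ``sd_floor_quantile`` percentile
    of pooled SDs (pass ``sd_floor=0`` to disable flooring).

    Mild-group samples never enter this statistic.
    """
    if len(control_ids) < 2 or len(severe_ids) < 2:
        raise ValueError("each group needs >= 2 samples for the t-statistic")
    m = track.matrix
    ci = [m.samples.index(s) for s in control_ids]
    si = [m.samples.index(s) for s in severe_ids]
    sc, ss = track.smoothed[:, ci], track.smoothed[:, si]
    mc, ms = sc.mean(axis=1), ss.mean(axis=1)
    n1, n2 = len(ci), len(si)
    v1 = sc.var(axis=1, ddof=1)
    v2 = ss.var(axis=1, ddof=1)
    sd_pool = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if sd_floor is None:
        sd_floor = float(np.quantile(sd_pool, sd_floor_quantile))
    denom = np.maximum(sd_pool, sd_floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (ms - mc) / denom, 0.0)

    raw_c = m.beta[:, ci].mean(axis=1)
    raw_s = m.beta[:, si].mean(axis=1)
    return TStatTrack(
        matrix=m,
        t=t,
        mean_control=mc,
        mean_severe=ms,
        raw_delta=raw_s - raw_c,
        control_ids=list(control_ids),
        severe_ids=list(severe_ids),
        sd_floor=float(sd_floor),
    )


def t_thresholds(t: np.ndarray, quantile: float = 0.05) -> tuple[float, float]:
    """Symmetric empirical tail thresholds: (lower, upper) cutting off
    quantile/2 of the t distribution in each tail."""
    lo, hi = np.quantile(t, [quantile / 2.0, 1.0 - quantile / 2.0])
    return float(lo), float(hi)


def _region_group_means(
    matrix: FilteredMatrix, lo: int, hi: int, control_ids, severe_ids
) -> tuple[float, float]:
    """Group means of per-sample mean raw beta over CpG rows [lo, hi)."""
    ci = [matrix.samples.index(s) for s in control_ids]
    si = [matrix.samples.index(s) for s in severe_ids]
    per_sample = np.nanmean(matrix.beta[lo:hi], axis=0)
    return float(per_sample[ci].mean()), float(per_sample[si].mean())


def call_candidate_dmrs(
    track: TStatTrack,
    quantile: float = 0.05,
    min_delta: float = 0.10,
    min_cpg: int = 3,
    max_gap: int = 300,
) -> list[DMR]:
    """Candidate DMRs: maximal runs of same-sign CpGs in the extreme tails
    of the t distribution, with successive member CpGs <= max_gap apart,
    kept iff the run has >= min_cpg members and the region's raw group
    methylation difference is >= min_delta in magnitude.
    """
    if len(track.t) == 0:
        return []
    thr_lo, thr_hi = t_thresholds(track.t, quantile)
    return _call_runs(track, thr_lo, thr_hi, min_delta, min_cpg, max_gap)


def _call_runs(track, thr_lo, thr_hi, min_delta, min_cpg, max_gap) -> list[DMR]:
    m = track.matrix
    chroms = m.index["chrom"].to_numpy()
    positions = m.index["pos"].to_numpy()
    sign = np.where(track.t >= thr_hi, 1, np.where(track.t <= thr_lo, -1, 0))

    dmrs: list[DMR] = []
    counter = 0
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        members = sel[sign[sel] != 0]
        if len(members) == 0:
            continue
        runs: list[list[int]] = [[members[0]]]
        for prev, cur in zip(members, members[1:]):
            same_sign = sign[prev] == sign[cur]
            close = positions[cur] - positions[prev] <= max_gap
            if same_sign and close:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            if len(run) < min_cpg:
                continue
            lo_row, hi_row = run[0], run[-1] + 1
            mean_c, mean_s = _region_group_means(
                m, lo_row, hi_row, track.control_ids, track.severe_ids
            )
            delta = mean_s - mean_c
            if abs(delta) < min_delta:
                continue
            counter += 1
            dmrs.append(
                DMR(
                    id=f"dmr_{counter:05d}",
                    chrom=str(chrom),
                    start=int(positions[lo_row]),
                    end=int(positions[hi_row - 1]) + 1,
                    n_cpg=len(run),
                    mean_beta_control=mean_c,
                    mean_beta_severe=mean_s,
                    delta=delta,
                    direction="hyper" if delta > 0 else "hypo",
                    area=float(track.t[run].sum()),
                )
            )
    return dmrs


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumeration over group assignments.

    Ranks are tie-averaged; the p-value is the fraction of the C(n1+n2, n1)
    assignments whose rank sum deviates from its mean at least as much as
    the observed one.  Falls back to the normal approximation when both
    groups exceed 10 samples.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 > 10 and n2 > 10:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        w = ranks[list(comb)].sum()
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def _per_sample_region_means(matrix: FilteredMatrix, chrom: str, start: int, end: int):
    chroms = matrix.index["chrom"].to_numpy()
    positions = matrix.index["pos"].to_numpy()
    rows = np.flatnonzero((chroms == chrom) & (positions >= start) & (positions < end))
    if len(rows) == 0:
        return None, 0
    return np.nanmean(matrix.beta[rows], axis=0), len(rows)


def wilcoxon_filter(
    dmrs: list[DMR],
    matrix: FilteredMatrix,
    control_ids: list[str],
    severe_ids: list[str],
    alpha: float = 0.1,
) -> list[DMR]:
    """Exact two-sided rank-sum filter on per-sample raw DMR mean betas
    (control vs severe); regions with p >= alpha are removed.  No multiple-
    testing correction is applied, matching the intended use as a
    false-positive guard on candidates rather than a discovery test.
    """
    ci = [matrix.samples.index(s) for s in control_ids]
    si = [matrix.samples.index(s) for s in severe_ids]
    kept = []
    for d in dmrs:
        means, n_rows = _per_sample_region_means(matrix, d.chrom, d.start, d.end)
        if means is None or np.isnan(means[ci]).all() or np.isnan(means[si]).all():
            logger.warning("%s: no covered CpGs in a group, dropped", d.id)
            continue
        p = exact_ranksum_p(means[ci], means[si])
        d.wilcoxon_p = p
        d.passed_wilcoxon = p < alpha
        if d.passed_wilcoxon:
            kept.append(d)
    return kept


def stitch(
    dmrs: list[DMR],
    matrix: FilteredMatrix,
    control_ids: list[str],
    severe_ids: list[str],
    max_join_gap: int = 5000,
    min_delta: float = 0.10,
    guard: str = "difference",
    member_signs: tuple | None = None,
) -> list[DMR]:
    """Greedily merge adjacent same-direction DMRs < max_join_gap apart,
    iterated to a fixpoint.

    A merge is accepted only if the merged span's guard holds:
    ``guard='difference'`` (default) requires |group mean-beta difference|
    >= min_delta over the merged span; ``guard='level'`` is the literal
    reading (merged mean methylation level >= min_delta).  ``member_signs``
    optionally carries (t, thr_lo, thr_hi) so intervening tail CpGs inside
    the merged span count toward n_cpg.
    """
    if guard not in {"difference", "level"}:
        raise ValueError("guard must be 'difference' or 'level'")
    work = sorted(dmrs, key=lambda d: (d.chrom, d.start))
    changed = True
    while changed:
        changed = False
        out: list[DMR] = []
        i = 0
        while i < len(work):
            cur = work[i]
            if i + 1 < len(work):
                nxt = work[i + 1]
                gap = nxt.start - cur.end
                if (
                    cur.chrom == nxt.chrom
                    and cur.direction == nxt.direction
                    and 0 <= gap < max_join_gap
                ):
                    merged = _try_merge(
                        cur, nxt, matrix, control_ids, severe_ids,
                        min_delta, guard, member_signs,
                    )
                    if merged is not None:
                        out.append(merged)
                        i += 2
                        changed = True
                        continue
            out.append(cur)
            i += 1
        work = out
    return work


def _try_merge(cur, nxt, matrix, control_ids, severe_ids, min_delta, guard,
               member_signs):
    chroms = matrix.index["chrom"].to_numpy()
    positions = matrix.index["pos"].to_numpy()
    rows = np.flatnonzero(
        (chroms == cur.chrom) & (positions >= cur.start) & (positions < nxt.end)
    )
    mean_c, mean_s = _region_group_means(
        matrix, rows[0], rows[-1] + 1, control_ids, severe_ids
    )
    delta = mean_s - mean_c
    if guard == "difference":
        if abs(delta) < min_delta:
            return None
    else:
        if (mean_c + mean_s) / 2.0 < min_delta:
            return None
    n_cpg = cur.n_cpg + nxt.n_cpg
    if member_signs is not None:
        t, thr_lo, thr_hi = member_signs
        between = np.flatnonzero(
            (chroms == cur.chrom) & (positions >= cur.end) & (positions < nxt.start)
        )
        want = 1 if cur.direction == "hyper" else -1
        sign = np.where(t[between] >= thr_hi, 1,
                        np.where(t[between] <= thr_lo, -1, 0))
        n_cpg += int((sign == want).sum())
    provenance = (cur.stitched_from or [cur.id]) + (nxt.stitched_from or [nxt.id])
    return DMR(
        id=cur.id,
        chrom=cur.chrom,
        start=cur.start,
        end=nxt.end,
        n_cpg=n_cpg,
        mean_beta_control=mean_c,
        mean_beta_severe=mean_s,
        delta=delta,
        direction=cur.direction,
        area=cur.area + nxt.area,
        wilcoxon_p=min(cur.wilcoxon_p, nxt.wilcoxon_p),
        passed_wilcoxon=cur.passed_wilcoxon and nxt.passed_wilcoxon,
        stitched_from=provenance,
    )


def direction_shares(n_hyper: int, n_hypo: int, decimals: int = 0):
    """Percentages of hyper- and hypomethylated regions among all regions."""
    total = n_hyper + n_hypo
    if total == 0:
        return 0.0, 0.0
    hyper = round(100.0 * n_hyper / total, decimals)
    hypo = round(100.0 * n_hypo / total, decimals)
    if decimals == 0:
        return int(hyper), int(hypo)
    return hyper, hypo


def summarize(dmrs: list[DMR], decimals: int = 0) -> dict:
    """Counts, direction shares, mean CpG count and mean length."""
    n_hyper = sum(d.direction == "hyper" for d in dmrs)
    n_hypo = sum(d.direction == "hypo" for d in dmrs)
    pct_hyper, pct_hypo = direction_shares(n_hyper, n_hypo, decimals)
    n = len(dmrs)
    return {
        "n_total": n,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": pct_hyper,
        "pct_hypo": pct_hypo,
        "mean_n_cpg": float(np.mean([d.n_cpg for d in dmrs])) if n else 0.0,
        "mean_length": float(np.mean([d.length for d in dmrs])) if n else 0.0,
    }


def dmr_sample_beta(dmrs: list[DMR], matrix: FilteredMatrix) -> pd.DataFrame:
    """Per-sample mean raw beta for every DMR (rows = DMR ids)."""
    rows = {}
    for d in dmrs:
        means, _ = _per_sample_region_means(matrix, d.chrom, d.start, d.end)
        rows[d.id] = means if means is not None else np.full(len(matrix.samples), np.nan)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.samples)


def cluster_dmrs(beta_df: pd.DataFrame, k: int = 2, seed: int = 0) -> pd.Series:
    """k-means grouping of DMRs by their cross-sample beta profile; used to
    project mild-group donors onto regions called from control vs severe."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(beta_df.to_numpy())
    return pd.Series(labels, index=beta_df.index, name="cluster")


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom, "start": d.start, "end": d.end, "name": d.id,
                "score": d.area, "strand": ".", "n_cpg": d.n_cpg,
                "delta": d.delta, "direction": d.direction,
                "wilcoxon_p": d.wilcoxon_p,
            }
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "n_cpg", "delta", "direction", "wilcoxon_p"],
    )


def write_dmr_bed(dmrs: list[DMR], path) -> None:
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", header=False, index=False)


def read_dmr_bed(path) -> list[DMR]:
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "n_cpg", "delta", "direction", "wilcoxon_p"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols,
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return []
    out = []
    for _, r in df.iterrows():
        out.append(
            DMR(
                id=str(r["name"]), chrom=str(r["chrom"]), start=int(r["start"]),
                end=int(r["end"]), n_cpg=int(r["n_cpg"]),
                mean_beta_control=math.nan, mean_beta_severe=math.nan,
                delta=float(r["delta"]), direction=str(r["direction"]),
                area=float(r["score"]), wilcoxon_p=float(r["wilcoxon_p"]),
                passed_wilcoxon=True,
            )
        )
    return out
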