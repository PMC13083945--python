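"""Simplified negative-binomial differential expression.

Counts are normalized by median-of-ratios size factors; per gene, a
two-group NB model with log link is summarized by a Wald statistic on the
group log-ratio, with gene-wise method-of-moments dispersions shrunk
halfway toward a fitted mean-dispersion trend (a0 + a1/mean).  This is a
deliberately simplified caller: no IRLS dispersion MLE, no LFC shrinkage,
no independent filtering.  DEGs are genes with BH-adjusted p < 0.1 and
|log2 fold change| > 0.5.

The Wald statistic is referred to the standard normal, the conventional
reference for NB Wald tests.  The moment dispersion estimate (pooled
within groups, shrunk toward the trend) is mildly conservative at 3-5
donors per group, which offsets the usual small-sample anticonservatism of
plug-in standard errors; null simulations in the test suite check the
resulting type-I error calibration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MEAN_FLOOR = 0.5   # half a normalized count; guards logs and SEs at zero means


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with nonzero counts in all
    samples."""
    c = counts.to_numpy(float)
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider a "
            "pseudo-reference normalization"
        )
    ref = c[allpos]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.median(sf)   # convention: median size factor is 1
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts / sf


def _moment_dispersion(q: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion per gene, pooled within groups:
    alpha = (var - mean) / mean^2, floored at ~0."""
    n_genes = q.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    dof = 0
    for idx in group_idx:
        sub = q[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (var - mu)
        den += w * mu**2
        dof += w
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.clip(alpha, 1e-8, 10.0)


def _trend_dispersion(mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mean, evaluated at each gene."""
    ok = mean > 0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    a0, a1 = coef
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mean, MEAN_FLOOR)
    return np.clip(trend, 1e-8, 10.0)


def de_test(
    counts: pd.DataFrame,
    groups: dict[str, str],
    reference: str = "control",
    treatment: str = "severe",
    alpha: float = 0.1,
    lfc_min: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test of treatment vs reference.

    Returns a DataFrame indexed by gene with base_mean, log2_fc, p, padj and
    a DEG flag (padj < alpha and |log2_fc| > lfc_min).  All-zero genes are
    excluded from testing and from the BH denominator.
    """
    ref_ids = [s for s in counts.columns if groups.get(s) == reference]
    trt_ids = [s for s in counts.columns if groups.get(s) == treatment]
    if len(ref_ids) < 2 or len(trt_ids) < 2:
        raise ValueError("each group needs >= 2 samples")
    used = ref_ids + trt_ids
    sub = counts[used]
    sf = size_factors(sub)
    q = (sub / sf).to_numpy(float)
    nonzero = sub.to_numpy().sum(axis=1) > 0

    i_ref = np.arange(len(ref_ids))
    i_trt = np.arange(len(ref_ids), len(used))
    alpha_mom = _moment_dispersion(q, [i_ref, i_trt])
    base_mean = q.mean(axis=1)
    alpha_trend = _trend_dispersion(base_mean, alpha_mom)
    disp = 0.5 * alpha_mom + 0.5 * alpha_trend

    m_ref = np.maximum(q[:, i_ref].mean(axis=1), MEAN_FLOOR)
    m_trt = np.maximum(q[:, i_trt].mean(axis=1), MEAN_FLOOR)
    log2_fc = np.log2(m_trt / m_ref)

    # Var(log mean-hat) by the delta method; per-sample NB variance on the
    # normalized scale is mu/sf + disp * mu^2
    inv_sf_ref = np.mean([1.0 / sf[s] for s in ref_ids])
    inv_sf_trt = np.mean([1.0 / sf[s] for s in trt_ids])
    var_log_ref = (m_ref * inv_sf_ref + disp * m_ref**2) / (len(ref_ids) * m_ref**2)
    var_log_trt = (m_trt * inv_sf_trt + disp * m_trt**2) / (len(trt_ids) * m_trt**2)
    se = np.sqrt(var_log_ref + var_log_trt)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, np.log(m_trt / m_ref) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "stat": wald,
            "p": np.where(nonzero, p, np.nan),
        },
        index=counts.index,
    )
    out["padj"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "padj"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["deg"] = (out["padj"] < alpha) & (out["log2_fc"].abs() > lfc_min)
    out["deg"] = out["deg"].fillna(False)
    return out


def combine_deg_sets(de_a: pd.DataFrame, de_b: pd.DataFrame) -> dict:
    """Union / intersection of DEG flags from two contrasts over the same
    gene universe."""
    if not de_a.index.equals(de_b.index):
        raise ValueError("DE results must share the same gene universe")
    a = set(de_a.index[de_a["deg"]])
    b = set(de_b.index[de_b["deg"]])
    return {
        "set_a": a,
        "set_b": b,
        "union": a | b,
        "intersection": a & b,
        "n_a": len(a),
        "n_b": len(b),
        "n_union": len(a | b),
        "n_intersection": len(a & b),
    }


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0).replace(0, 1.0)
    return matrix.sub(mu, axis=0).div(sd, axis=0)


def _som_1d(X: np.ndarray, k: int, seed: int, n_iter: int = 500) -> np.ndarray:
    """Train a 1 x k self-organizing map on rows of X and return the
    winning-node index per row.

    Gaussian neighbourhood over node index; radius decays linearly from k/2
    to 0.5 and the learning rate from 0.5 to 0.01.
    """
    rng = np.random.default_rng(seed)
    nodes = X[rng.choice(len(X), size=k, replace=len(X) < k)].astype(float)
    r0, r1 = k / 2.0, 0.5
    l0, l1 = 0.5, 0.01
    order = rng.integers(0, len(X), size=n_iter)
    for t, i in enumerate(order):
        frac = t / max(n_iter - 1, 1)
        radius = r0 + (r1 - r0) * frac
        lr = l0 + (l1 - l0) * frac
        x = X[i]
        bmu = int(np.argmin(((nodes - x) ** 2).sum(axis=1)))
        dist = np.arange(k) - bmu
        h = np.exp(-(dist**2) / (2.0 * radius**2))
        nodes += lr * h[:, None] * (x - nodes)
    d = ((X[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


def archetype_cluster(
    deg_matrix: pd.DataFrame, k: int = 3, method: str = "som", seed: int = 0
) -> pd.Series:
    """Cluster z-scored DEG expression profiles into k archetypes with a
    1 x k SOM (default) or k-means (``method='kmeans'``)."""
    if k > len(deg_matrix):
        raise ValueError("k exceeds the number of genes to cluster")
    X = deg_matrix.to_numpy(float)
    if method == "som":
        labels = _som_1d(X, k, seed)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=k, n_init=k, random_state=seed).fit_predict(X)
    else:
        raise ValueError("method must be 'som' or 'kmeans'")
    return pd.Series(labels, index=deg_matrix.index, name="cluster")
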