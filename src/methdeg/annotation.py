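"""Genomic-feature annotation and region-based enrichment.

Regions (typically DMRs) are labelled by the feature at their midpoint with
the precedence promoter-TSS > TTS > exon > intron > intergenic, compared to
a genome-wide label distribution, overlapped with chromatin-state tilings
against a GC- and length-matched sampled background, and assigned to genes
by nearest TSS within 100 kb for gene-set enrichment in the GREAT style
(binomial over regions AND hypergeometric over genes, fold >= 2, FDR < 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FEATURE_PRECEDENCE = ["promoter-TSS", "TTS", "exon", "intron", "intergenic"]


def gene_tss(genes: pd.DataFrame) -> np.ndarray:
    """Strand-aware TSS coordinate: 5' end of the gene span."""
    plus = genes["strand"].to_numpy() == "+"
    return np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy() - 1)


def gene_tts(genes: pd.DataFrame) -> np.ndarray:
    plus = genes["strand"].to_numpy() == "+"
    return np.where(plus, genes["end"].to_numpy() - 1, genes["start"].to_numpy())


def annotate_features(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = (-1000, 100),
    tts_window: tuple[int, int] = (-100, 1000),
) -> pd.Series:
    """Label each region by its midpoint feature.

    Windows are relative to the strand-aware TSS/TTS (negative = upstream in
    gene orientation).  Precedence: promoter-TSS > TTS > exon > intron >
    intergenic.
    """
    if genes.empty:
        raise ValueError("gene models must be non-empty")
    tss = gene_tss(genes)
    tts = gene_tts(genes)
    plus = genes["strand"].to_numpy() == "+"
    gchrom = genes["chrom"].to_numpy()
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    exons = list(genes["exons"]) if "exons" in genes.columns else [[] for _ in range(len(genes))]

    def window_bounds(anchor, rel_lo, rel_hi, is_plus):
        # reflect the window for minus-strand genes
        lo = np.where(is_plus, anchor + rel_lo, anchor - rel_hi)
        hi = np.where(is_plus, anchor + rel_hi, anchor - rel_lo)
        return lo, hi

    prom_lo, prom_hi = window_bounds(tss, *promoter_window, plus)
    tts_lo, tts_hi = window_bounds(tts, *tts_window, plus)

    labels = []
    mids = ((regions["start"] + regions["end"]) // 2).to_numpy()
    rchrom = regions["chrom"].to_numpy()
    for mid, chrom in zip(mids, rchrom):
        on = gchrom == chrom
        if ((on) & (prom_lo <= mid) & (mid <= prom_hi)).any():
            labels.append("promoter-TSS")
            continue
        if ((on) & (tts_lo <= mid) & (mid <= tts_hi)).any():
            labels.append("TTS")
            continue
        in_gene = on & (gstart <= mid) & (mid < gend)
        if in_gene.any():
            in_exon = any(
                s <= mid < e
                for gi in np.flatnonzero(in_gene)
                for (s, e) in exons[gi]
            )
            labels.append("exon" if in_exon else "intron")
            continue
        labels.append("intergenic")
    return pd.Series(labels, index=regions.index, name="feature")


def feature_enrichment(labels_fg: pd.Series, labels_genome: pd.Series) -> pd.DataFrame:
    """Per-feature enrichment of foreground labels against a genome-wide
    label distribution: log2 fold of proportions, two-sided exact binomial
    p, BH-adjusted q."""
    if len(labels_fg) == 0 or len(labels_genome) == 0:
        raise ValueError("label sets must be non-empty")
    fg = labels_fg.value_counts()
    bg = labels_genome.value_counts()
    fg_total, bg_total = int(fg.sum()), int(bg.sum())
    rows = []
    for feat in sorted(set(fg.index) | set(bg.index)):
        k, b = int(fg.get(feat, 0)), int(bg.get(feat, 0))
        if b == 0:
            fold, p = np.nan, np.nan
        else:
            p0 = b / bg_total
            with np.errstate(divide="ignore"):
                fold = float(np.log2((k / fg_total) / p0)) if k else -np.inf
            p = stats.binomtest(k, fg_total, p0, alternative="two-sided").pvalue
        rows.append(
            {"feature": feat, "fg_count": k, "fg_total": fg_total,
             "bg_count": b, "bg_total": bg_total, "log2_fold": fold, "p": p}
        )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def _merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


class _ExclusionIndex:
    """Sorted, merged intervals per chromosome for fast overlap queries."""

    def __init__(self, regions: pd.DataFrame | None):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if regions is None or len(regions) == 0:
            return
        for chrom, grp in regions.groupby("chrom"):
            merged = _merge_intervals(zip(grp["start"], grp["end"]))
            starts = np.array([s for s, _ in merged])
            ends = np.array([e for _, e in merged])
            self.by_chrom[str(chrom)] = (starts, ends)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.by_chrom:
            return False
        starts, ends = self.by_chrom[chrom]
        i = np.searchsorted(starts, end, side="left")
        return bool(i > 0 and ends[i - 1] > start)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def sample_gc_matched_background(
    regions: pd.DataFrame,
    genome_seq: dict[str, str],
    n: int = 50_000,
    gc_tol: float = 0.02,
    exclusion: pd.DataFrame | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Draw n random regions, length- and GC-matched to the foreground,
    avoiding the exclusion set.

    Foreground regions are cycled; for each, uniform candidates of the same
    length are drawn until the GC difference is <= gc_tol and the candidate
    misses the exclusion intervals.  After ``max_tries`` failures the
    tolerance is doubled with a warning; failing twice more raises.
    """
    if not len(regions):
        raise ValueError("empty foreground")
    excl = _ExclusionIndex(exclusion)
    rng = np.random.default_rng(seed)
    chrom_names = list(genome_seq)
    lengths = np.array([len(genome_seq[c]) for c in chrom_names], dtype=float)
    weights = lengths / lengths.sum()

    fg = regions.reset_index(drop=True)
    fg_gc = [
        gc_fraction(genome_seq[r["chrom"]][int(r["start"]):int(r["end"])])
        if r["chrom"] in genome_seq else np.nan
        for _, r in fg.iterrows()
    ]
    rows = []
    failed = []
    for i in range(n):
        r = fg.iloc[i % len(fg)]
        target_gc = fg_gc[i % len(fg)]
        length = int(r["end"] - r["start"])
        tol = gc_tol
        placed = False
        for doubling in range(3):
            for _ in range(max_tries):
                ci = int(rng.choice(len(chrom_names), p=weights))
                chrom = chrom_names[ci]
                limit = len(genome_seq[chrom]) - length
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit))
                end = start + length
                if excl.overlaps(chrom, start, end):
                    continue
                gc = gc_fraction(genome_seq[chrom][start:end])
                if np.isnan(target_gc) or abs(gc - target_gc) <= tol:
                    rows.append({"chrom": chrom, "start": start, "end": end,
                                 "gc": gc, "matched_to": int(i % len(fg))})
                    placed = True
                    break
            if placed:
                break
            tol *= 2
            warnings.warn(
                f"background sampling: doubled GC tolerance to {tol:.3f} "
                f"for foreground region {i % len(fg)}"
            )
        if not placed:
            failed.append(int(i % len(fg)))
    if failed:
        raise RuntimeError(
            f"could not place GC-matched background for foreground regions {sorted(set(failed))}"
        )
    return pd.DataFrame(rows)


def _state_overlap_bp(regions: pd.DataFrame, states: pd.DataFrame) -> dict[str, int]:
    """bp of region overlap per chromatin state (states partition the genome)."""
    out: dict[str, int] = {}
    by_chrom = {str(c): g.sort_values("start") for c, g in states.groupby("chrom")}
    for _, r in regions.iterrows():
        chrom = str(r["chrom"])
        if chrom not in by_chrom:
            continue
        seg = by_chrom[chrom]
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        labels = seg["state"].to_numpy()
        lo = np.searchsorted(ends, int(r["start"]), side="right")
        hi = np.searchsorted(starts, int(r["end"]), side="left")
        for j in range(lo, hi):
            ov = min(int(r["end"]), int(ends[j])) - max(int(r["start"]), int(starts[j]))
            if ov > 0:
                out[labels[j]] = out.get(labels[j], 0) + ov
    return out


def state_enrichment(
    regions: pd.DataFrame, states: pd.DataFrame, background: pd.DataFrame
) -> pd.DataFrame:
    """Per-state bp-weighted enrichment of foreground regions over a sampled
    background: fraction of overlapping bases per state, log2 fold, binomial
    p on the fg bp count against the background fraction, BH q."""
    fg_bp = _state_overlap_bp(regions, states)
    bg_bp = _state_overlap_bp(background, states)
    fg_total = sum(fg_bp.values())
    bg_total = sum(bg_bp.values())
    rows = []
    for state in sorted(set(states["state"])):
        k = fg_bp.get(state, 0)
        b = bg_bp.get(state, 0)
        if b == 0 or fg_total == 0 or bg_total == 0:
            fold, p = np.nan, np.nan
        else:
            p0 = b / bg_total
            with np.errstate(divide="ignore"):
                fold = float(np.log2((k / fg_total) / p0)) if k else -np.inf
            p = stats.binomtest(k, fg_total, p0, alternative="two-sided").pvalue
        rows.append(
            {"state": state, "fg_bp": k, "fg_total_bp": fg_total,
             "bg_bp": b, "bg_total_bp": bg_total, "log2_fold": fold, "p": p}
        )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def great_assign(
    regions: pd.DataFrame, genes: pd.DataFrame, max_dist: int = 100_000
) -> pd.DataFrame:
    """Assign each region to the gene with nearest TSS (by |TSS - region
    midpoint|) within max_dist; ties break to the lexicographically smaller
    gene_id.  Unassignable regions get gene_id = None."""
    tss = gene_tss(genes)
    gid = genes["gene_id"].to_numpy()
    gchrom = genes["chrom"].to_numpy()
    rows = []
    for idx, r in regions.iterrows():
        mid = (int(r["start"]) + int(r["end"])) // 2
        on = gchrom == r["chrom"]
        if not on.any():
            rows.append({"region_index": idx, "gene_id": None, "distance": np.nan})
            continue
        d = np.abs(tss[on] - mid)
        best = d.min()
        if best > max_dist:
            rows.append({"region_index": idx, "gene_id": None, "distance": np.nan})
            continue
        cand = sorted(gid[on][d == best])
        rows.append({"region_index": idx, "gene_id": cand[0], "distance": int(best)})
    return pd.DataFrame(rows)


@dataclass
class RegulatoryDomains:
    """Per-gene regulatory domain (TSS +- max_dist, clipped to chromosome)."""

    domains: pd.DataFrame        # gene_id, chrom, start, end

    @classmethod
    def build(cls, genes: pd.DataFrame, chrom_lengths: dict[str, int],
              max_dist: int = 100_000):
        tss = gene_tss(genes)
        rows = []
        for (_, g), t in zip(genes.iterrows(), tss):
            L = chrom_lengths.get(g["chrom"], int(t) + max_dist)
            rows.append(
                {"gene_id": g["gene_id"], "chrom": g["chrom"],
                 "start": max(0, int(t) - max_dist), "end": min(L, int(t) + max_dist)}
            )
        return cls(pd.DataFrame(rows))

    def coverage_bp(self, gene_ids=None) -> int:
        d = self.domains
        if gene_ids is not None:
            d = d[d["gene_id"].isin(set(gene_ids))]
        total = 0
        for _, grp in d.groupby("chrom"):
            for s, e in _merge_intervals(zip(grp["start"], grp["end"])):
                total += e - s
        return total


def region_geneset_enrichment(
    links: pd.DataFrame,
    gene_sets: dict[str, set],
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int],
    max_dist: int = 100_000,
    fdr: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """GREAT-style gene-set enrichment of region-gene links.

    Region-based binomial: a linked region counts as a hit for a set if its
    gene is a member; the null hit probability is the fraction of the total
    regulatory-domain coverage contributed by the set's genes.  Gene-based
    hypergeometric: genes with >= 1 linked region, drawn from the gene
    universe.  Reported sets must pass BH-FDR < fdr in BOTH tests and have a
    region fold >= min_fold.
    """
    doms = RegulatoryDomains.build(genes, chrom_lengths, max_dist)
    total_bp = doms.coverage_bp()
    linked = links[links["gene_id"].notna()]
    n_regions = len(linked)
    genes_with_region = set(linked["gene_id"])
    universe = set(genes["gene_id"])
    rows = []
    for name, members in gene_sets.items():
        members = members & universe
        if not members:
            logger.warning("gene set %s empty after intersecting universe; skipped", name)
            continue
        set_bp = doms.coverage_bp(members)
        p_hit = set_bp / total_bp if total_bp else 0.0
        k_regions = int(linked["gene_id"].isin(members).sum())
        fold = (k_regions / n_regions) / p_hit if (n_regions and p_hit) else 0.0
        p_binom = (
            stats.binomtest(k_regions, n_regions, p_hit, alternative="greater").pvalue
            if n_regions else np.nan
        )
        k_genes = len(members & genes_with_region)
        p_hyper = stats.hypergeom.sf(
            k_genes - 1, len(universe), len(members), len(genes_with_region)
        )
        rows.append(
            {"set": name, "region_hits": k_regions, "regions_total": n_regions,
             "gene_hits": k_genes, "set_size": len(members),
             "region_fold": fold, "p_binomial": p_binom, "p_hypergeom": p_hyper}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q_binomial"] = out["q_hypergeom"] = out["reported"] = []
        return out
    out["q_binomial"] = multipletests(out["p_binomial"].fillna(1.0), method="fdr_bh")[1]
    out["q_hypergeom"] = multipletests(out["p_hypergeom"], method="fdr_bh")[1]
    out["reported"] = (
        (out["q_binomial"] < fdr)
        & (out["q_hypergeom"] < fdr)
        & (out["region_fold"] >= min_fold)
    )
    return out
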