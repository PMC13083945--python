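"""Methylation-expression integration.

DMRs are linked to genes three ways — promoter-proximal (TSS +- 6 kb
overlap), nearest gene within 100 kb, and enhancer-mediated through a
GeneHancer-style association table filtered in four stages (element
overlap, coding/lncRNA gene, Elite score, differentially expressed gene).
Each link is scored by the Spearman correlation between per-donor DMR mean
methylation and normalized expression across all donors, classified
negative (rho < -0.5) or positive (rho > 0.5), tested for DMR
overrepresentation at DEGs with Fisher's exact test, and master regulators
of an interaction network are ranked by exact betweenness centrality.
"""

from __future__ import annotations

import logging
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotation import gene_tss
from .dmr import DMR

logger = logging.getLogger(__name__)

RHO_CUTOFF = 0.5


def assign_promoter_dmrs(
    dmrs: list[DMR], genes: pd.DataFrame, window: int = 6000
) -> pd.DataFrame:
    """Link every DMR to every gene whose TSS +- window interval it
    overlaps.  Distance is DMR midpoint minus TSS, signed in gene
    orientation (positive = downstream of the TSS)."""
    tss = gene_tss(genes)
    rows = []
    for d in dmrs:
        on = genes["chrom"].to_numpy() == d.chrom
        lo = tss - window
        hi = tss + window
        hit = on & (d.start <= hi) & (d.end > lo)
        mid = (d.start + d.end) // 2
        for gi in np.flatnonzero(hit):
            offset = mid - int(tss[gi])
            if genes["strand"].iloc[gi] == "-":
                offset = -offset
            rows.append(
                {"dmr_id": d.id, "gene_id": genes["gene_id"].iloc[gi],
                 "link_type": "promoter", "distance": offset,
                 "direction": d.direction}
            )
    return pd.DataFrame(
        rows, columns=["dmr_id", "gene_id", "link_type", "distance", "direction"]
    )


def dmr_deg_fisher(links: pd.DataFrame, de_result: pd.DataFrame):
    """Fisher's exact test of DMR-link overrepresentation at DEGs.

    Rows of the 2x2 table: DEG / non-DEG; columns: has >= 1 linked DMR /
    none.  The universe is the tested genes of the DE result.  Returns
    ``(table, odds_ratio, p)``.
    """
    tested = de_result[de_result["p"].notna()]
    linked = set(links["gene_id"]) & set(tested.index)
    deg = set(tested.index[tested["deg"]])
    a = len(deg & linked)
    b = len(deg - linked)
    c = len(linked - deg)
    d = len(tested.index) - a - b - c
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        warnings.warn("degenerate 2x2 margin; Fisher p set to 1")
        return table, math.nan, 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def classify_rho(rho: float, cutoff: float = RHO_CUTOFF) -> str:
    if math.isnan(rho):
        return "unclassified"
    if rho < -cutoff:
        return "negative"
    if rho > cutoff:
        return "positive"
    return "unclassified"


def correlate_links(
    links: pd.DataFrame,
    dmr_beta: pd.DataFrame,
    normalized_expr: pd.DataFrame,
    cutoff: float = RHO_CUTOFF,
) -> pd.DataFrame:
    """Spearman correlation (average ranks for ties) between per-donor DMR
    mean beta and normalized expression over the donors shared by both
    matrices; classification at +-cutoff."""
    shared = [s for s in dmr_beta.columns if s in normalized_expr.columns]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples for correlation")
    out = links.copy()
    rhos, classes = [], []
    for _, row in links.iterrows():
        if row["dmr_id"] not in dmr_beta.index or row["gene_id"] not in normalized_expr.index:
            rhos.append(math.nan)
            classes.append("unclassified")
            continue
        x = dmr_beta.loc[row["dmr_id"], shared].to_numpy(float)
        y = normalized_expr.loc[row["gene_id"], shared].to_numpy(float)
        rho = _spearman(x, y)
        rhos.append(rho)
        classes.append(classify_rho(rho, cutoff))
    out["spearman_rho"] = rhos
    out["corr_class"] = classes
    return out


def class_shares(n_negative: int, n_positive: int, decimals: int = 1):
    """Shares (in %) of negative and positive classes among classified links."""
    total = n_negative + n_positive
    if total == 0:
        return math.nan, math.nan
    return (
        round(100.0 * n_negative / total, decimals),
        round(100.0 * n_positive / total, decimals),
    )


def linked_share(n_linked: int, n_total: int, decimals: int = 1) -> float:
    """Share (in %) of genes carrying at least one link."""
    if n_total == 0:
        return math.nan
    return round(100.0 * n_linked / n_total, decimals)


def correlation_summary(links: pd.DataFrame, de_result: pd.DataFrame | None = None) -> dict:
    """Counts and percentages of negative/positive correlation classes among
    DEG-linked genes, plus the share of all DEGs carrying a link."""
    work = links
    if de_result is not None:
        deg = set(de_result.index[de_result["deg"]])
        work = links[links["gene_id"].isin(deg)]
    by_gene = work.groupby("gene_id")["corr_class"].agg(
        lambda s: "negative" if (s == "negative").any()
        else ("positive" if (s == "positive").any() else "unclassified")
    )
    n_neg = int((by_gene == "negative").sum())
    n_pos = int((by_gene == "positive").sum())
    pct_neg, pct_pos = class_shares(n_neg, n_pos)
    out = {
        "n_negative": n_neg,
        "n_positive": n_pos,
        "n_unclassified": int((by_gene == "unclassified").sum()),
        "pct_negative": pct_neg,
        "pct_positive": pct_pos,
    }
    if de_result is not None:
        n_deg = int(de_result["deg"].sum())
        out["n_deg"] = n_deg
        out["n_deg_linked"] = int(by_gene.size)
        out["pct_deg_linked"] = linked_share(by_gene.size, n_deg)
    return out


def enhancer_cascade(
    dmrs: list[DMR], enhancers: pd.DataFrame, de_result: pd.DataFrame
):
    """Four-stage enhancer-mediated linking.

    Stage 1: DMR-element associations (DMR interval overlaps the element);
    stage 2: associations whose gene is protein_coding or lncRNA;
    stage 3: Elite associations only;
    stage 4: associations whose gene is differentially expressed.
    Returns ``(links, stage_counts)`` where stage_counts also records the
    number of distinct DMRs overlapping any element.
    """
    deg = set(de_result.index[de_result["deg"]])
    assoc = []
    dmr_hit = set()
    for d in dmrs:
        on = enhancers[enhancers["chrom"] == d.chrom]
        hit = on[(on["start"] < d.end) & (on["end"] > d.start)]
        for _, e in hit.iterrows():
            dmr_hit.add(d.id)
            assoc.append(
                {"dmr_id": d.id, "element_id": e["element_id"],
                 "gene_id": e["gene_id"], "biotype": e["biotype"],
                 "score": e["score"], "elite": bool(e["elite"]),
                 "link_type": "enhancer", "direction": d.direction}
            )
    stage1 = pd.DataFrame(
        assoc, columns=["dmr_id", "element_id", "gene_id", "biotype",
                        "score", "elite", "link_type", "direction"]
    )
    stage2 = stage1[stage1["biotype"].isin({"protein_coding", "lncRNA"})]
    stage3 = stage2[stage2["elite"].astype(bool)]
    stage4 = stage3[stage3["gene_id"].isin(deg)]
    counts = {
        "associations": len(stage1),
        "dmrs_overlapping": len(dmr_hit),
        "coding_or_lncRNA": len(stage2),
        "elite": len(stage3),
        "deg_linked": len(stage4),
    }
    return stage4.reset_index(drop=True), counts


def master_regulator_rank(
    edges: list[tuple[str, str]], node_annotations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Rank nodes of an (undirected, simple) interaction network by exact
    betweenness centrality (unnormalized shortest-path pair counts).

    Annotations (e.g. DEG flag, log2 fold change, negative-correlation
    flag), indexed by node, are passed through.  Ties share a rank.
    """
    g = nx.Graph()
    g.add_edges_from(edges)
    if node_annotations is not None:
        g.add_nodes_from(node_annotations.index)
    bc = nx.betweenness_centrality(g, normalized=False)
    out = pd.DataFrame(
        {"node": list(bc), "betweenness": [bc[n] for n in bc]}
    ).set_index("node")
    if node_annotations is not None:
        out = out.join(node_annotations, how="left")
    out["rank"] = out["betweenness"].rank(ascending=False, method="min").astype(int)
    return out.sort_values(["rank", "node"])
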