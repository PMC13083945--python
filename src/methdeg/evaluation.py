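"""Planted-truth evaluation studies on synthetic data.

These drive the package end to end against generators with known ground
truth: planted-DMR recovery (sensitivity at reciprocal overlap, false-call
rate), differential-expression null calibration, and recovery of planted
negative methylation-expression links.

The DMR recovery study runs on a scaled-down two-chromosome genome
(~20,000 CpGs).  Analysis parameters are scaled accordingly: the smoothing
half-window stays at the 1 kb default but the minimum window occupancy is
20 CpGs (not the 70 used genome-wide) and the t tail quantile is 1.5%
(about 1% of CpGs carry planted signal, so 5% tails would be dominated by
noise CpGs at this genome size).
"""

from __future__ import annotations

import numpy as np

from . import dmr, expression, integration, io, synthetic

RECOVERY_SMOOTH_H = 1000
RECOVERY_SMOOTH_MIN_CPGS = 20
RECOVERY_T_QUANTILE = 0.015


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """min(overlap/len(a), overlap/len(b)) for (chrom, start, end) tuples."""
    if a[0] != b[0]:
        return 0.0
    ov = min(a[2], b[2]) - max(a[1], b[1])
    if ov <= 0:
        return 0.0
    return min(ov / (a[2] - a[1]), ov / (b[2] - b[1]))


def call_dmrs_scaled(matrix, control_ids, severe_ids,
                     h=RECOVERY_SMOOTH_H, min_cpgs_window=RECOVERY_SMOOTH_MIN_CPGS,
                     quantile=RECOVERY_T_QUANTILE):
    """Full DMR-calling chain (smooth -> t -> candidates -> rank-sum filter
    -> stitch) with the scaled-down analysis parameters."""
    track = dmr.smooth(matrix, h=h, min_cpgs_window=min_cpgs_window)
    tstat = dmr.group_tstat(track, control_ids, severe_ids)
    candidates = dmr.call_candidate_dmrs(tstat, quantile=quantile)
    kept = dmr.wilcoxon_filter(candidates, matrix, control_ids, severe_ids)
    thr = dmr.t_thresholds(tstat.t, quantile)
    return dmr.stitch(kept, matrix, control_ids, severe_ids,
                      member_signs=(tstat.t, *thr))


def simulate_study(seed: int, n_effects: int = 20, n_cpg_per_effect: int = 10,
                   delta: float = 0.3, coverage_mean: float = 10.0,
                   chrom_length: int = 1_000_000, link_sign: str = "none"):
    """The standard planted study: 2 x 1 Mb genome, 3 control / 3 mild /
    5 severe donors, evenly planted alternating hypo/hyper regions."""
    layout, genes = synthetic.simulate_genome(
        n_chrom=2, chrom_length=chrom_length, mean_cpg_spacing=100, seed=seed
    )
    design = synthetic.StudyDesign.default()
    effects = synthetic.plant_effects_evenly(
        layout, n_effects, n_cpg_per_effect, delta=delta, baseline_mu=0.6,
        genes=genes if link_sign != "none" else None, link_sign=link_sign,
        seed=seed,
    )
    callsets = synthetic.simulate_methylation(
        layout, design, effects, coverage_mean=coverage_mean, dispersion=30.0,
        seed=seed,
    )
    return layout, genes, design, effects, callsets


def dmr_recovery_study(seeds, min_reciprocal: float = 0.5) -> dict:
    """Sensitivity and false-call rate of the DMR caller on planted data,
    averaged over seeds."""
    sens_list, false_list = [], []
    for seed in seeds:
        _, _, design, effects, callsets = simulate_study(int(seed))
        matrix = io.filter_cpgs(list(callsets.values()))
        called = call_dmrs_scaled(
            matrix, design.ids("control"), design.ids("severe")
        )
        planted = [(e.chrom, e.start, e.end) for e in effects]
        called_iv = [(d.chrom, d.start, d.end) for d in called]
        recovered = sum(
            any(reciprocal_overlap(c, p) >= min_reciprocal for c in called_iv)
            for p in planted
        )
        false = sum(
            all(reciprocal_overlap(c, p) == 0.0 for p in planted)
            for c in called_iv
        )
        sens_list.append(recovered / len(planted))
        false_list.append(false / len(called_iv) if called_iv else 0.0)
    return {
        "sensitivity": float(np.mean(sens_list)),
        "false_call_rate": float(np.mean(false_list)),
        "n_seeds": len(list(seeds)),
    }


def dmr_null_filter_study(seeds) -> dict:
    """With no planted effects: mean number of candidate regions before and
    after the rank-sum filter (the filter must remove candidates)."""
    pre, post = [], []
    for seed in seeds:
        layout, _, design, _, _ = None, None, None, None, None
        layout, genes = synthetic.simulate_genome(
            n_chrom=2, chrom_length=500_000, mean_cpg_spacing=100, seed=int(seed)
        )
        design = synthetic.StudyDesign.default()
        callsets = synthetic.simulate_methylation(
            layout, design, [], coverage_mean=10.0, dispersion=30.0, seed=int(seed)
        )
        matrix = io.filter_cpgs(list(callsets.values()))
        track = dmr.smooth(matrix, h=RECOVERY_SMOOTH_H,
                           min_cpgs_window=RECOVERY_SMOOTH_MIN_CPGS)
        tstat = dmr.group_tstat(track, design.ids("control"), design.ids("severe"))
        candidates = dmr.call_candidate_dmrs(tstat, quantile=RECOVERY_T_QUANTILE)
        kept = dmr.wilcoxon_filter(
            candidates, matrix, design.ids("control"), design.ids("severe")
        )
        pre.append(len(candidates))
        post.append(len(kept))
    return {"mean_candidates": float(np.mean(pre)),
            "mean_after_filter": float(np.mean(post))}


def de_null_calibration(seeds, n_genes: int = 2000) -> float:
    """Fraction of raw p-values < 0.05 under the expression null (no
    planted effects), averaged over seeds."""
    fractions = []
    for seed in seeds:
        layout, genes = synthetic.simulate_genome(
            n_chrom=1, chrom_length=200_000, mean_cpg_spacing=200,
            n_genes_per_chrom=n_genes, seed=int(seed),
        )
        design = synthetic.StudyDesign.default()
        callsets = synthetic.simulate_methylation(
            layout, design, [], coverage_mean=10.0, dispersion=30.0, seed=int(seed)
        )
        counts = synthetic.simulate_expression(
            genes, callsets, [], nb_dispersion=0.05, seed=int(seed)
        )
        res = expression.de_test(counts, design.groups)
        p = res["p"].dropna()
        fractions.append(float((p < 0.05).mean()))
    return float(np.mean(fractions))


def negative_link_recovery(seeds, n_links: int = 20) -> dict:
    """Fraction of planted negative methylation-expression links classified
    'negative', and the classification rate among unlinked gene-DMR pairs."""
    recovered, spurious = [], []
    for seed in seeds:
        layout, genes, design, effects, callsets = simulate_study(
            int(seed), n_effects=n_links, link_sign="negative"
        )
        counts = synthetic.simulate_expression(
            genes, callsets, effects, nb_dispersion=0.05, slope=8.0, seed=int(seed)
        )
        norm = expression.normalize(counts)
        samples = list(counts.columns)
        rows = {}
        for i, e in enumerate(effects):
            beta = synthetic.region_mean_beta(callsets, e.chrom, e.start, e.end)
            rows[f"planted_{i}"] = [beta[s] for s in samples]
        import pandas as pd

        dmr_beta = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        links = pd.DataFrame(
            [
                {"dmr_id": f"planted_{i}", "gene_id": e.linked_gene}
                for i, e in enumerate(effects) if e.linked_gene
            ]
        )
        out = integration.correlate_links(links, dmr_beta, norm)
        recovered.append(float((out["corr_class"] == "negative").mean()))

        # unlinked pairs: same DMRs against genes with no planted link
        linked_genes = {e.linked_gene for e in effects}
        free_genes = [g for g in genes["gene_id"] if g not in linked_genes][:n_links]
        null_links = pd.DataFrame(
            [
                {"dmr_id": f"planted_{i}", "gene_id": g}
                for i, g in enumerate(free_genes)
            ]
        )
        null_out = integration.correlate_links(null_links, dmr_beta, norm)
        spurious.append(float((null_out["corr_class"] != "unclassified").mean()))
    return {
        "recovered_fraction": float(np.mean(recovered)),
        "spurious_fraction": float(np.mean(spurious)),
    }
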