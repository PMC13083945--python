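"""Orchestration of the full analysis as independently runnable stages.

Stages write plain-text outputs into a run directory and a machine-readable
manifest (config hash, seed, versions, per-stage record counts).  Each
stage reads the files earlier stages produced, so the pipeline can be
re-entered at any point on pre-existing files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, dmr, expression, integration, io, motifs, synthetic
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "dmr", "enrich", "motif", "de", "integrate"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing input file {path}")
    return path


def _write_genes(genes: pd.DataFrame, path: Path) -> None:
    g = genes.copy()
    g["exons"] = g["exons"].apply(
        lambda ex: ";".join(f"{s}-{e}" for s, e in ex)
    )
    g.to_csv(path, sep="\t", index=False)


def _read_genes(path: Path) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    g["exons"] = g["exons"].fillna("").apply(
        lambda s: [tuple(map(int, x.split("-"))) for x in s.split(";") if x]
    )
    return g


def _load_design(workdir: Path, stage: str) -> synthetic.StudyDesign:
    meta = pd.read_csv(_require(workdir / "metadata.tsv", stage), sep="\t")
    return synthetic.StudyDesign(list(meta.itertuples(index=False, name=None)))


def _load_matrix(workdir: Path, cfg: PipelineConfig, stage: str) -> io.FilteredMatrix:
    design = _load_design(workdir, stage)
    callsets = [
        io.read_bismark_coverage(
            _require(workdir / "meth" / f"{sid}.cov.tsv", stage), sid
        )
        for sid in design.ids()
    ]
    return io.filter_cpgs(
        callsets, min_cov=cfg.min_cov, top_cov_fraction=cfg.top_cov_fraction
    )


def stage_simulate(cfg: PipelineConfig, workdir: Path) -> dict:
    """Generate the full synthetic study into the run directory."""
    layout, genes = synthetic.simulate_genome(
        n_chrom=cfg.n_chrom, chrom_length=cfg.chrom_length,
        mean_cpg_spacing=cfg.mean_cpg_spacing, seed=cfg.seed,
    )
    design = synthetic.StudyDesign.default(cfg.n_control, cfg.n_mild, cfg.n_severe)
    effects = synthetic.plant_effects_evenly(
        layout, cfg.n_effects, cfg.n_cpg_per_effect, delta=cfg.effect_delta,
        baseline_mu=cfg.effect_baseline, genes=genes, link_sign="negative",
        seed=cfg.seed,
    )
    callsets = synthetic.simulate_methylation(
        layout, design, effects, coverage_mean=cfg.coverage_mean,
        dispersion=cfg.bb_dispersion, seed=cfg.seed,
    )
    counts = synthetic.simulate_expression(
        genes, callsets, effects, nb_dispersion=cfg.nb_dispersion,
        slope=cfg.expr_slope, seed=cfg.seed,
    )
    annot = synthetic.simulate_annotations(layout, effects, seed=cfg.seed)
    genome = synthetic.simulate_sequence(layout, seed=cfg.seed)

    (workdir / "meth").mkdir(parents=True, exist_ok=True)
    (workdir / "motifs").mkdir(exist_ok=True)
    synthetic.write_metadata(design, workdir / "metadata.tsv")
    for sid, cs in callsets.items():
        io.write_bismark_coverage(cs, workdir / "meth" / f"{sid}.cov.tsv")
    _write_genes(genes, workdir / "genes.tsv")
    counts.rename_axis("gene_id").to_csv(workdir / "counts.tsv", sep="\t")
    synthetic.write_bed(
        annot["states"], workdir / "states.bed", cols=("chrom", "start", "end")
    )
    annot["enhancers"].to_csv(workdir / "enhancers.tsv", sep="\t", index=False)
    synthetic.write_fasta(annot["sequences"], workdir / "region_sequences.fa")
    synthetic.write_fasta(genome, workdir / "genome.fa")
    for name, label, matrix in annot["motifs"]:
        synthetic.write_pwm(name, label, matrix, workdir / "motifs" / f"{name}.pwm")
    pd.DataFrame(
        [
            {"chrom": e.chrom, "start": e.start, "end": e.end,
             "direction": e.direction, "delta": e.delta,
             "linked_gene": e.linked_gene or "", "link_sign": e.link_sign}
            for e in effects
        ]
    ).to_csv(workdir / "planted_effects.tsv", sep="\t", index=False)
    with open(workdir / "region_groups.json", "w") as fh:
        json.dump(
            {"foreground": annot["foreground_names"],
             "background": annot["background_names"]}, fh,
        )
    return {
        "n_cpg": layout.n_cpg, "n_samples": len(design.samples),
        "n_genes": len(genes), "n_effects": len(effects),
    }


def stage_qc(cfg: PipelineConfig, workdir: Path) -> dict:
    design = _load_design(workdir, "qc")
    if len(design.samples) < 2:
        raise StageError("qc", "PCA requires at least 2 samples")
    matrix = _load_matrix(workdir, cfg, "qc")
    out = workdir / "qc"
    out.mkdir(exist_ok=True)
    deciles = io.decile_frequency(matrix, design.groups)
    deciles.to_csv(out / "decile_frequency.tsv", sep="\t", index=False)
    n_top = min(50_000, matrix.n_cpg)
    scores, frac = io.pca_variable_cpgs(matrix, n_top=n_top)
    pd.DataFrame(
        scores, index=matrix.samples,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    ).rename_axis("sample_id").to_csv(out / "pca_scores.tsv", sep="\t")
    pd.Series(frac, name="variance_fraction").to_csv(out / "pca_variance.tsv", sep="\t")
    matrix.to_frame().to_csv(workdir / "filtered_matrix.tsv", sep="\t", index=False)
    return {"n_cpg_retained": matrix.n_cpg}


def stage_dmr(cfg: PipelineConfig, workdir: Path) -> dict:
    design = _load_design(workdir, "dmr")
    matrix = _load_matrix(workdir, cfg, "dmr")
    ctrl, sev = design.ids("control"), design.ids("severe")
    track = dmr.smooth(matrix, h=cfg.smooth_h, min_cpgs_window=cfg.smooth_min_cpgs)
    tstat = dmr.group_tstat(track, ctrl, sev, sd_floor_quantile=cfg.sd_floor_quantile)
    candidates = dmr.call_candidate_dmrs(
        tstat, quantile=cfg.t_quantile, min_delta=cfg.min_delta,
        min_cpg=cfg.min_cpg, max_gap=cfg.max_gap,
    )
    kept = dmr.wilcoxon_filter(candidates, matrix, ctrl, sev, alpha=cfg.wilcoxon_alpha)
    thr = dmr.t_thresholds(tstat.t, cfg.t_quantile)
    stitched = dmr.stitch(
        kept, matrix, ctrl, sev, max_join_gap=cfg.stitch_gap,
        min_delta=cfg.min_delta, guard=cfg.stitch_guard,
        member_signs=(tstat.t, *thr),
    )
    out = workdir / "dmr"
    out.mkdir(exist_ok=True)
    dmr.write_dmr_bed(stitched, out / "dmrs.bed")
    summary = dmr.summarize(stitched)
    pd.Series(summary).to_csv(out / "summary.tsv", sep="\t", header=False)
    beta = dmr.dmr_sample_beta(stitched, matrix)
    beta.rename_axis("dmr_id").to_csv(out / "dmr_beta.tsv", sep="\t")
    return {"n_candidates": len(candidates), "n_after_wilcoxon": len(kept),
            "n_dmrs": len(stitched)}


def stage_enrich(cfg: PipelineConfig, workdir: Path) -> dict:
    genes = _read_genes(_require(workdir / "genes.tsv", "enrich"))
    dmrs = dmr.read_dmr_bed(_require(workdir / "dmr" / "dmrs.bed", "enrich"))
    regions = dmr.dmrs_to_frame(dmrs)[["chrom", "start", "end"]]
    states = pd.read_csv(
        _require(workdir / "states.bed", "enrich"), sep="\t", header=None,
        names=["chrom", "start", "end", "state"], dtype={"chrom": str},
    )
    genome = motifs.read_fasta(_require(workdir / "genome.fa", "enrich"))
    out = workdir / "enrich"
    out.mkdir(exist_ok=True)
    if regions.empty:
        for name in ("features.tsv", "feature_enrichment.tsv",
                     "state_enrichment.tsv", "great_links.tsv"):
            (out / name).write_text("")
        return {"n_regions": 0}
    labels = annotation.annotate_features(regions, genes)
    labels.to_csv(out / "features.tsv", sep="\t", header=True)
    # genome-wide background: the chromatin-state tiling segments stand in
    # for an unbiased genomic label distribution
    genome_regions = states[["chrom", "start", "end"]]
    genome_labels = annotation.annotate_features(genome_regions, genes)
    annotation.feature_enrichment(labels, genome_labels).to_csv(
        out / "feature_enrichment.tsv", sep="\t", index=False
    )
    background = annotation.sample_gc_matched_background(
        regions, genome, n=min(cfg.background_n, 200 * len(regions)),
        gc_tol=cfg.gc_tol, exclusion=regions, seed=cfg.seed,
    )
    annotation.state_enrichment(regions, states, background).to_csv(
        out / "state_enrichment.tsv", sep="\t", index=False
    )
    links = annotation.great_assign(regions, genes, max_dist=cfg.great_distance)
    links["dmr_id"] = [dmrs[i].id for i in links["region_index"]]
    links.to_csv(out / "great_links.tsv", sep="\t", index=False)
    background.to_csv(out / "background_regions.tsv", sep="\t", index=False)
    return {"n_regions": len(regions), "n_great_links": int(links["gene_id"].notna().sum())}


def stage_motif(cfg: PipelineConfig, workdir: Path) -> dict:
    sequences = motifs.read_fasta(_require(workdir / "region_sequences.fa", "motif"))
    with open(_require(workdir / "region_groups.json", "motif")) as fh:
        groups = json.load(fh)
    motif_models = [
        motifs.read_pwm(p) for p in sorted((workdir / "motifs").glob("*.pwm"))
    ]
    if not motif_models:
        raise StageError("motif", "no PWM files found under motifs/")
    fg = {n: sequences[n] for n in groups["foreground"]}
    bg = {n: sequences[n] for n in groups["background"]}
    fg_hits = pd.DataFrame({m.name: motifs.scan_zoops(fg, m) for m in motif_models})
    bg_hits = pd.DataFrame({m.name: motifs.scan_zoops(bg, m) for m in motif_models})
    result = motifs.enrichment_test(fg_hits, bg_hits, motif_models)
    out = workdir / "motif"
    out.mkdir(exist_ok=True)
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return {"n_motifs": len(motif_models), "n_fg": len(fg), "n_bg": len(bg)}


def stage_de(cfg: PipelineConfig, workdir: Path) -> dict:
    design = _load_design(workdir, "de")
    counts = pd.read_csv(
        _require(workdir / "counts.tsv", "de"), sep="\t", index_col=0
    )
    de_severe = expression.de_test(
        counts, design.groups, treatment="severe",
        alpha=cfg.de_alpha, lfc_min=cfg.lfc,
    )
    de_mild = expression.de_test(
        counts, design.groups, treatment="mild",
        alpha=cfg.de_alpha, lfc_min=cfg.lfc,
    )
    combined = expression.combine_deg_sets(de_mild, de_severe)
    out = workdir / "de"
    out.mkdir(exist_ok=True)
    de_severe.rename_axis("gene_id").to_csv(out / "de_severe.tsv", sep="\t")
    de_mild.rename_axis("gene_id").to_csv(out / "de_mild.tsv", sep="\t")
    with open(out / "deg_overlap.json", "w") as fh:
        json.dump({k: v for k, v in combined.items() if k.startswith("n_")}, fh)
    degs = sorted(combined["union"])
    if len(degs) >= cfg.k:
        norm = expression.normalize(counts)
        z = expression.zscore_rows(norm.loc[degs])
        clusters = expression.archetype_cluster(z, k=cfg.k, seed=cfg.seed)
        clusters.rename_axis("gene_id").to_csv(out / "clusters.tsv", sep="\t")
    norm = expression.normalize(counts)
    norm.rename_axis("gene_id").to_csv(out / "normalized_counts.tsv", sep="\t")
    return {"n_deg_severe": int(de_severe["deg"].sum()),
            "n_deg_mild": int(de_mild["deg"].sum()),
            "n_deg_union": combined["n_union"]}


def stage_integrate(cfg: PipelineConfig, workdir: Path) -> dict:
    genes = _read_genes(_require(workdir / "genes.tsv", "integrate"))
    dmrs = dmr.read_dmr_bed(_require(workdir / "dmr" / "dmrs.bed", "integrate"))
    de_severe = pd.read_csv(
        _require(workdir / "de" / "de_severe.tsv", "integrate"), sep="\t", index_col=0
    )
    out = workdir / "integrate"
    out.mkdir(exist_ok=True)
    if not dmrs:
        pd.DataFrame(
            columns=["dmr_id", "gene_id", "link_type", "distance",
                     "spearman_rho", "corr_class"]
        ).to_csv(out / "links.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({"n_negative": 0, "n_positive": 0, "n_links": 0}, fh)
        return {"n_links": 0}
    links = integration.assign_promoter_dmrs(dmrs, genes, window=cfg.promoter_window)
    dmr_beta = pd.read_csv(
        _require(workdir / "dmr" / "dmr_beta.tsv", "integrate"), sep="\t", index_col=0
    )
    norm = pd.read_csv(
        _require(workdir / "de" / "normalized_counts.tsv", "integrate"),
        sep="\t", index_col=0,
    )
    links = integration.correlate_links(links, dmr_beta, norm, cutoff=cfg.rho_cutoff)
    links.to_csv(out / "links.tsv", sep="\t", index=False)
    table, odds, fisher_p = integration.dmr_deg_fisher(links, de_severe)
    summary = integration.correlation_summary(links, de_severe)
    summary.update({"fisher_odds": odds, "fisher_p": fisher_p,
                    "n_links": len(links)})
    enhancers = pd.read_csv(_require(workdir / "enhancers.tsv", "integrate"), sep="\t")
    cascade_links, stage_counts = integration.enhancer_cascade(dmrs, enhancers, de_severe)
    cascade_links.to_csv(out / "enhancer_links.tsv", sep="\t", index=False)
    summary["enhancer_cascade"] = stage_counts
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, default=float)
    # simple correlation-derived network: genes sharing a DMR are connected
    neg = links[links["corr_class"] == "negative"]
    edges = [
        (a, b)
        for _, grp in neg.groupby("dmr_id")
        for a in grp["gene_id"] for b in grp["gene_id"] if a < b
    ]
    annotations = pd.DataFrame({"deg": de_severe["deg"], "log2_fc": de_severe["log2_fc"]})
    if edges:
        integration.master_regulator_rank(edges, annotations.loc[
            sorted({n for e in edges for n in e})
        ]).to_csv(out / "network_rank.tsv", sep="\t")
    return {"n_links": len(links), "fisher_p": fisher_p,
            "cascade": stage_counts}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "dmr": stage_dmr,
    "enrich": stage_enrich,
    "motif": stage_motif,
    "de": stage_de,
    "integrate": stage_integrate,
}


def run_stage(name: str, cfg: PipelineConfig, workdir) -> dict:
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}")
    cfg.validate()
    return _STAGE_FUNCS[name](cfg, Path(workdir))


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(cfg: PipelineConfig, workdir, stages=None) -> dict:
    """Execute the pipeline end to end; returns the manifest.

    A failing stage aborts the run with the stage named; outputs of earlier
    stages are retained in the run directory.
    """
    cfg.validate()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": {},
    }
    for name in stages or STAGES:
        t0 = time.time()
        try:
            counts = run_stage(name, cfg, workdir)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        logger.info("stage %s done in %.1fs: %s", name, time.time() - t0, counts)
        manifest["stages"][name] = counts
    with open(workdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "methdeg": "0.1.0",
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }
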