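"""Pipeline configuration: one flat key-value schema covering every stage.

Defaults mirror the analysis procedure: 4x minimum coverage, 0.1% top-
coverage trim, BSmooth-style smoothing (+-1 kb, >= 70 CpGs per window), 5%
most-extreme t threshold, >= 10% methylation difference, >= 3 CpGs within
300 bp, Wilcoxon alpha 0.1, < 5 kb stitching, TSS +- 6 kb promoter window,
100 kb nearest-gene distance, 50,000 GC-matched background regions, 0.7
motif probability cutoff, DE at FDR 10% with |log2FC| > 0.5, |rho| > 0.5
correlation classes, k = 3 expression archetypes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # site filtering
    min_cov: int = 4
    top_cov_fraction: float = 0.001
    # smoothing / t-statistic
    smooth_h: int = 1000
    smooth_min_cpgs: int = 70
    sd_floor_quantile: float = 0.75
    # DMR calling
    t_quantile: float = 0.05
    min_delta: float = 0.10
    min_cpg: int = 3
    max_gap: int = 300
    wilcoxon_alpha: float = 0.1
    stitch_gap: int = 5000
    stitch_guard: str = "difference"
    # annotation / enrichment
    promoter_window: int = 6000
    great_distance: int = 100_000
    background_n: int = 50_000
    gc_tol: float = 0.02
    # motifs
    motif_cutoff: float = 0.7
    # differential expression
    de_alpha: float = 0.1
    lfc: float = 0.5
    # integration
    rho_cutoff: float = 0.5
    k: int = 3
    # simulation (the synthetic study conditions)
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    mean_cpg_spacing: int = 100
    n_control: int = 3
    n_mild: int = 3
    n_severe: int = 5
    n_effects: int = 20
    n_cpg_per_effect: int = 40
    effect_delta: float = 0.3
    effect_baseline: float = 0.6
    coverage_mean: float = 10.0
    bb_dispersion: float = 30.0
    nb_dispersion: float = 0.05
    expr_slope: float = 8.0
    # global
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.min_cov >= 1, "min_cov must be >= 1"),
            (0 <= self.top_cov_fraction < 1, "top_cov_fraction in [0, 1)"),
            (self.smooth_h > 0, "smooth_h must be positive"),
            (self.smooth_min_cpgs >= 1, "smooth_min_cpgs must be >= 1"),
            (0 < self.t_quantile < 1, "t_quantile in (0, 1)"),
            (0 <= self.min_delta <= 1, "min_delta in [0, 1]"),
            (self.min_cpg >= 1, "min_cpg must be >= 1"),
            (self.max_gap > 0, "max_gap must be positive"),
            (0 < self.wilcoxon_alpha <= 1, "wilcoxon_alpha in (0, 1]"),
            (self.stitch_gap > 0, "stitch_gap must be positive"),
            (self.stitch_guard in {"difference", "level"}, "bad stitch_guard"),
            (self.promoter_window >= 0, "promoter_window must be >= 0"),
            (self.great_distance > 0, "great_distance must be positive"),
            (self.background_n >= 1, "background_n must be >= 1"),
            (0 < self.motif_cutoff < 1, "motif_cutoff in (0, 1)"),
            (0 < self.de_alpha <= 1, "de_alpha in (0, 1]"),
            (self.lfc >= 0, "lfc must be >= 0"),
            (0 < self.rho_cutoff < 1, "rho_cutoff in (0, 1)"),
            (self.k >= 1, "k must be >= 1"),
            (self.mean_cpg_spacing >= 2, "mean_cpg_spacing must be >= 2"),
            (self.coverage_mean >= 1, "coverage_mean must be >= 1"),
            (self.bb_dispersion > 0, "bb_dispersion must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)
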