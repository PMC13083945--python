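import numpy as np
import pandas as pd
import pytest

from methdeg import synthetic
from methdeg.io import FilteredMatrix


def make_matrix(positions, beta, cov=None, chrom="chr1", samples=None):
    """Build a FilteredMatrix from raw arrays (test helper)."""
    beta = np.asarray(beta, float)
    if beta.ndim == 1:
        beta = beta[:, None]
    if cov is None:
        cov = np.full_like(beta, 10.0)
    else:
        cov = np.asarray(cov, float)
        if cov.ndim == 1:
            cov = np.tile(cov[:, None], (1, beta.shape[1]))
    if samples is None:
        samples = [f"s{i}" for i in range(beta.shape[1])]
    index = pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions, int)})
    return FilteredMatrix(index=index, beta=beta, cov=cov, samples=list(samples))


@pytest.fixture
def small_study():
    """A compact planted study shared across modules: 2 x 300 kb genome,
    default 3/3/5 design, 6 planted regions with negative expression links."""
    layout, genes = synthetic.simulate_genome(
        n_chrom=2, chrom_length=300_000, mean_cpg_spacing=100, seed=11
    )
    design = synthetic.StudyDesign.default()
    effects = synthetic.plant_effects_evenly(
        layout, 6, 10, delta=0.3, baseline_mu=0.6, genes=genes,
        link_sign="negative", seed=11,
    )
    callsets = synthetic.simulate_methylation(
        layout, design, effects, coverage_mean=10, dispersion=30, seed=11
    )
    return layout, genes, design, effects, callsets


@pytest.fixture
def toy_genes():
    """Two genes on opposite strands with exons, plus a distal lncRNA."""
    return pd.DataFrame(
        [
            {"gene_id": "GA", "chrom": "chr1", "strand": "+", "start": 10_000,
             "end": 16_000, "biotype": "protein_coding",
             "exons": [(10_000, 11_000), (15_000, 16_000)]},
            {"gene_id": "GB", "chrom": "chr1", "strand": "-", "start": 40_000,
             "end": 48_000, "biotype": "protein_coding",
             "exons": [(40_000, 41_000), (47_000, 48_000)]},
            {"gene_id": "GC", "chrom": "chr2", "strand": "+", "start": 5_000,
             "end": 9_000, "biotype": "lncRNA", "exons": [(5_000, 9_000)]},
        ]
    )
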