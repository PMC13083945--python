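"""Simulate a small bisulfite study and run the site-level QC.

Generates a 2 x 1 Mb genome with 3 control / 3 mild / 5 severe donors and
20 planted differentially methylated regions, applies the site filters
(>= 4x coverage in all samples, top 0.1% coverage trimmed, sex chromosomes
excluded), and prints the decile methylation-frequency distribution and the
leading principal components of the most variable CpGs.
"""

import numpy as np

from methdeg import io, synthetic

layout, genes = synthetic.simulate_genome(
    n_chrom=2, chrom_length=1_000_000, mean_cpg_spacing=100, seed=1
)
design = synthetic.StudyDesign.default()
effects = synthetic.plant_effects_evenly(
    layout, 20, 10, delta=0.3, baseline_mu=0.6, seed=1
)
callsets = synthetic.simulate_methylation(
    layout, design, effects, coverage_mean=10, dispersion=30, seed=1
)

matrix = io.filter_cpgs(list(callsets.values()))
print(f"CpGs simulated: {layout.n_cpg}, retained after filters: {matrix.n_cpg}")

deciles = io.decile_frequency(matrix, design.groups)
print("\nDecile frequencies (group means; rows are methylation bins):")
print(deciles.round(3).to_string(index=False))
print("-> most CpGs sit in the top bins (a methylated genome); the per-bin")
print("   Kruskal-Wallis p flags bins where the groups differ.")

scores, frac = io.pca_variable_cpgs(matrix, n_top=min(10_000, matrix.n_cpg))
print("\nPC1/PC2 variance fractions:", np.round(frac[:2], 3))
for s, row in zip(matrix.samples, scores):
    print(f"  {s:6s} PC1={row[0]:+.2f} PC2={row[1]:+.2f}")
print("-> severe donors separate from controls on PC1, driven by the")
print("   planted methylation differences; mild donors fall in between.")
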