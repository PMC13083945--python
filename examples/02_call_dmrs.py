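"""Call differentially methylated regions on data with planted truth.

Runs the full calling chain — local-linear smoothing, group t-statistic
with a variance floor, extreme-tail run candidates, the >= 10% difference
and >= 3 CpG filters, the exact rank-sum false-positive filter and < 5 kb
stitching — then scores recovery against the planted regions.
"""

from methdeg import dmr, evaluation, io, synthetic

layout, genes = synthetic.simulate_genome(2, 1_000_000, 100, seed=3)
design = synthetic.StudyDesign.default()
effects = synthetic.plant_effects_evenly(
    layout, 20, 10, delta=0.3, baseline_mu=0.6, seed=3
)
callsets = synthetic.simulate_methylation(
    layout, design, effects, coverage_mean=10, dispersion=30, seed=3
)
matrix = io.filter_cpgs(list(callsets.values()))

called = evaluation.call_dmrs_scaled(
    matrix, design.ids("control"), design.ids("severe")
)
summary = dmr.summarize(called)
print(f"called {summary['n_total']} DMRs: "
      f"{summary['pct_hypo']}% hypo / {summary['pct_hyper']}% hyper, "
      f"mean {summary['mean_n_cpg']:.1f} CpGs, mean {summary['mean_length']:.0f} bp")

planted = [(e.chrom, e.start, e.end) for e in effects]
recovered = sum(
    any(evaluation.reciprocal_overlap((d.chrom, d.start, d.end), p) >= 0.5
        for d in called)
    for p in planted
)
false = sum(
    all(evaluation.reciprocal_overlap((d.chrom, d.start, d.end), p) == 0
        for p in planted)
    for d in called
)
print(f"recovered {recovered}/{len(planted)} planted regions at >=50% "
      f"reciprocal overlap; {false} calls miss every planted region")
print("-> the caller finds planted 10-CpG, 30%-difference regions at "
      "coverage 10 with few noise calls.")
for d in called[:5]:
    print(f"  {d.id} {d.chrom}:{d.start}-{d.end} {d.direction} "
          f"delta={d.delta:+.2f} n_cpg={d.n_cpg} wilcoxon_p={d.wilcoxon_p:.3f}")
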