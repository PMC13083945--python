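# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical decisions made where the procedure left room.

## Site filtering and QC

CpGs are retained when total coverage is ≥ `min_cov` (default 4) in
*every* sample; CpGs whose coverage lies in the top `top_cov_fraction`
(default 0.001) quantile of any sample are then trimmed (PCR/mapping
artifacts), and sex chromosomes are dropped. The quantile is computed with
the "lower" interpolation so a single outlier above an otherwise flat
coverage distribution is always removed. Because a quantile cut re-applied
to already-trimmed data would keep shaving, refiltering a `FilteredMatrix`
skips the trim its provenance records as done — this is what makes the
filter idempotent.

Decile frequencies use left-closed bins with the final bin `[0.9, 1.0]`
closed (so β = 1 is countable) and are computed per sample; the per-bin
Kruskal–Wallis test across groups therefore has donor-level replicates.
PCA selects the `n_top` CpGs by variance of β (unweighted by coverage —
the simplest defensible ranking), centres without unit-variance scaling,
and uses an exact SVD.

## DMR calling

**Smoothing.** Each sample's β track is smoothed by a local-linear
weighted fit of β against genomic distance, evaluated at each CpG, with
weights tricube(distance) × total read count. The window is ±`h` (default
1000 bp), widened symmetrically to at least `min_cpgs_window` CpGs
(default 70). The linear term matters: a degree-0 weighted mean is biased
at sharp methylation steps and systematically truncates region boundaries;
the local-linear fit reproduces a linear ramp exactly and tracks step
edges. Degenerate windows (collinear positions) fall back to the weighted
mean; estimates are clipped to [0, 1]. Chromosomes with fewer than 3 CpGs
pass raw values through with a warning.

**t-statistic.** t = (smoothed severe mean − control mean) / max(pooled
within-group SD, floor), with the floor at the genome-wide 75th percentile
of pooled SDs. This is a signal-to-noise statistic (no √(1/n₁+1/n₂)
factor), so it has no reference distribution; thresholds are empirical
quantiles. The floor prevents near-zero SD estimates — inevitable with 3–5
samples per group — from dominating the tails. Mild-group donors never
enter the statistic; they are projected onto called regions afterwards.

**Candidates, filter, stitching.** Candidate regions are maximal runs of
same-sign CpGs in the `quantile` (default 0.05, split 2.5 % per tail) most
extreme t values, where successive *member* CpGs are ≤ 300 bp apart
(sub-threshold CpGs in between do not break a run but do count toward the
regional means). Candidates need ≥ 3 members and a raw-β group difference
|Δβ| ≥ 0.10; the difference is computed from unsmoothed values — using
smoothed values would be circular with the t statistic. The
false-positive filter is a two-sided rank-sum test on per-donor regional
mean β, exact by full enumeration over the C(n₁+n₂, n₁) group assignments
of tie-averaged ranks (the normal approximation is used only when both
groups exceed 10). Stitching merges same-direction neighbours < 5 kb apart
when the merged span keeps |Δβ| ≥ 0.10, iterated to a fixpoint. The merge
guard is read as a *difference* (a literal methylation-*level* guard,
which the wording also admits, would be vacuous for most regions; it is
available via `guard="level"`).

## Enrichment

Feature labels are assigned by region midpoint with precedence
promoter-TSS (−1000/+100 around the strand-aware TSS) > TTS (−100/+1000) >
exon > intron > intergenic. Feature and chromatin-state enrichment use
two-sided exact binomial tests against the background proportion with BH
correction; state overlap is bp-weighted. The sampled background matches
each foreground region in length and GC (tolerance 0.02, doubled with a
warning after 1000 failed draws, error after two doublings) and avoids an
exclusion set — normally the significant regions themselves, i.e., the
background is drawn from methylation-unchanged sequence. Nearest-gene
assignment takes the minimum |TSS − midpoint| within 100 kb, ties broken
to the lexicographically smaller gene id. Gene-set enrichment is
region-based: the null hit probability of a set is its genes'
regulatory-domain (TSS ± 100 kb, merged) share of the total domain
coverage; sets are reported when both the region binomial and the
gene hypergeometric pass BH-FDR < 0.05 with region fold ≥ 2.

## Motifs

The detection threshold of a position-probability matrix sums
ln(p_max/0.25) over positions whose consensus-base probability exceeds
0.7 — natural log, matching log-odds scanning; the consensus base is the
only reading that yields one number per position. Scanning floors matrix
entries at 10⁻³ before the log, scores N as 0, covers both strands, and
calls a ZOOPS hit when any window reaches the threshold. Enrichment is the
upper-tail hypergeometric on the pooled foreground+background urn;
sensitivity labels pass through untouched. GC composition is handled by
the matched background sampler rather than a scanner-internal correction.

## Differential expression

Size factors are median-of-ratios over genes with nonzero counts in all
samples, rescaled so the median factor is 1 (this makes "one doubled
sample → factor 2, others 1" exact; note that normalized counts then scale
with any global constant — only relative expression and the DE results are
scale-invariant). The Wald test uses normalized group means with a
delta-method SE from the NB variance μ/sf + αμ², where the gene dispersion
α is the within-group method-of-moments estimate shrunk 50/50 toward a
least-squares a₀ + a₁/μ trend. Group means are floored at half a
normalized count to keep logs and SEs finite for one-sided zeros;
all-zero genes are excluded from testing and from the BH denominator. The
statistic is referred to the standard normal: null simulations (2000
genes, 3 vs 5 donors, 10 seeds) give a raw-p < 0.05 fraction of ≈ 0.06,
whereas a t reference over-corrects to ≈ 0.02 because the moment
dispersion is itself conservative at these sample sizes. This caller is
deliberately simplified — no IRLS dispersion MLE, no LFC shrinkage, no
independent filtering — and its acceptance surface is simulation
calibration, not count-level parity with full-featured DE frameworks.

Archetype clustering is a 1 × k self-organizing map (Gaussian
neighbourhood, radius k/2 → 0.5 and learning rate 0.5 → 0.01 decaying
linearly over 500 iterations) on per-gene z-scores, with a k-means
fallback; k defaults to 3 (up-in-severe / down-in-severe / early
patterns).

## Integration

Promoter-proximal links are DMR-interval overlaps with TSS ± 6 kb; signed
distances are midpoint-to-TSS in gene orientation. Spearman ρ (average
ranks for ties) is computed across all donors of all three groups —
mild donors carry real information about intermediate states — with
classification at |ρ| > 0.5; zero-variance vectors are unclassified. Note
that the permutation null of Spearman's ρ at n = 11 puts ≈ 9 % of mass
beyond |ρ| = 0.5, so unlinked gene–DMR pairs are "classified" at roughly
that rate by construction; classification is descriptive, not a test.
DMR-at-DEG overrepresentation is Fisher's exact test on DEG × linked over
the tested-gene universe. The enhancer cascade applies four filters with
per-stage counts (associations → coding/lncRNA gene → Elite → DEG);
element–DMR overlaps are counted at the association level, with distinct
overlapping DMRs reported separately. Betweenness centrality is exact and
unnormalized on the undirected simplification of the interaction network
(edge types are not distinguished for path counting).

## Synthetic data: what it emulates, what it does not

The generator draws CpG positions with geometric gaps (mean spacing
100 bp), a bimodal mostly-methylated baseline (CpG-island-like lows), and
per-sample counts with Poisson totals (mean 10×) and beta-binomial
methylated counts at precision 30 (φ ≈ 0.03, mid-range of published WGBS
overdispersion estimates; at 10× coverage the binomial sampling noise
dominates this term anyway). Planted regions shift severe donors by the
full signed δ and each mild donor by a draw from {0, δ/2, δ}, emulating
mixed early-disease profiles. Planted windows are placed at locally
CpG-dense sites (all internal gaps ≤ 300 bp) because real DMRs sit at CpG
clusters — and because a "region" with an internal 400 bp gap is not one
region under the caller's own definition. Expression counts are NB with
log2 mean = baseline + slope × (donor region methylation − 0.5), slope
negative for repressive links; each planted effect links to its
nearest-TSS gene so the promoter-proximal chain can recover planted pairs.
Annotation fixtures tile chromosomes with labelled states, emit an
enhancer-association table over planted regions, and plant a consensus
motif in hypomethylated-region sequences at a configurable rate.

Not emulated: read-level data (FASTQ), bisulfite conversion error,
spatially correlated donor effects (each CpG draws its biological
deviation independently, so the rank-sum filter faces a milder null than
cell-composition artifacts would pose), copy number, SNPs, and library-
specific RNA-seq biases. Passing recovery tests on this generator shows
the pipeline's statistical machinery is correct at realistic noise levels;
it does not certify performance on artifact-laden real data.

## Scaled-down recovery studies

Recovery and calibration studies run on a 2 × 1 Mb genome (~20,000 CpGs)
with 20 planted 10-CpG regions — about 1 % of CpGs carry signal, the same
order as the genome-wide fraction a typical disease methylome shows. At
this genome size two analysis parameters are scaled from their genome-wide
defaults: the minimum smoothing-window occupancy is 20 CpGs (70 would
span ~7 kb here and dilute a 10-CpG region several-fold), and the t tail
quantile is 0.015 (5 % tails would admit ~4× more noise CpGs than there
are signal CpGs at n ≈ 20k, which no downstream filter at the pinned
0.10/0.1 settings can fully absorb). These choices were set by measuring
operating characteristics on seeds 1–10 and confirmed on held-out seeds
11–20 (sensitivity 0.92/0.94 at ≥ 50 % reciprocal overlap, false-call rate
0.06/0.09). Genome-wide defaults (h = 1000, ≥ 70 CpGs, quantile 0.05)
are untouched.

## Known limitations

- The exact rank-sum enumeration is O(C(n₁+n₂, n₁)) and is used up to
  group sizes of 10; beyond that the normal approximation applies.
- The smoother is O(total CpGs × window); genome-scale data (~28 M CpGs)
  would want the loop numba-compiled or chunk-parallelized.
- GC-matched sampling cycles foreground regions, so background draws are
  not independent across the cycle when n greatly exceeds the foreground.
- The SOM is a minimal 1D implementation adequate for k ≈ 3 archetypes;
  it is not a general SOM library.
- Enhancer tables are user-supplied; no regulatory-element content is
  bundled, and biotype/Elite semantics follow the documented table schema.
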