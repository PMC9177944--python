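# Methods

This note documents the statistical models behind `ifnsig`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## Study design assumed

A two-group cross-sectional cohort: healthy controls (`CTL`) and patients
(`FM`), with (i) gene-level RNA-seq counts from a sorted cell population,
(ii) a clinical table of symptom scores — widespread pain index (WPI,
0–19), symptom severity scale (SSS, 0–12), their sum the FM-score (0–31),
and the nine-item fatigue severity scale (items 1–7, reported as the sum,
9–63) — and (iii) a 92-protein Olink-style inflammation panel reported as
NPX values (relative log2 abundances). The reference cohort structure is
23 controls vs 25 patients, with a high-inflammatory subset of 7 patients.

## Expression preprocessing

Genes with zero counts in more than `max_zero_samples` (default 5) samples
are removed before any modelling; the retained-gene count is logged per
stage rather than asserted, since it depends on the cohort. Library-size
normalization is the median-of-ratios estimator: with geometric means
g_g = (∏_j k_gj)^{1/n} over the reference set of genes positive in every
sample, s_j = median_g k_gj/g_g. This reproduces the default behaviour of
the standard RNA-seq tooling; note the estimator is only scale-equivariant
in the *ratios* s_j/s_j' (multiplying one library by c moves every factor
by c^(1/n) through the geometric means). The log transform is
log2(k/s + 1); the +1 offset is configurable and recorded in output
metadata, since heatmap and score transforms are convention rather than
model.

Per-gene z-scores use the sample SD (ddof = 1) throughout, matching the
control-SD convention of the IFN score. Constant rows are dropped from
z-scoring with a warning — they carry no clustering information and would
corrupt Euclidean distances.

## Differential expression

The per-gene test is a transparent negative-binomial Wald test rather than
a wrap of the reference implementation; exact numerical agreement with
that tool's empirical-Bayes dispersion machinery is deliberately not
claimed, and correctness is assessed by simulation calibration instead.

With normalized counts q_gj = k_gj/s_j and the NB variance
Var(k) = μ + φμ², the moment estimator uses the pooled within-group
variance V_g: φ̂_g = (V_g − μ_g·mean(1/s))/μ_g², floored at 1e-8. Each φ̂_g
is shrunk toward a trend — the median moment dispersion in ~20
log10-baseMean quantile bins, interpolated — with weight 0.7 on the trend.
The log2 fold change uses group means with a 0.5 pseudocount (the
reference DEG table contains base means as low as 9.5, where raw ratios
are unstable); the Wald statistic log2FC/SE with a delta-method SE is
referred to the standard normal, two-sided. At the default cohort size
(23 + 25) the measured type-I error at α = 0.05 is ≈ 0.05 over null
simulations (acceptance keeps it inside [0.03, 0.07]).

Benjamini–Hochberg step-up adjustment is implemented directly (sorted
p·m/rank with a reverse cumulative minimum) and is the shared FDR routine
for the DE table, the NPX panel and GSEA; tests check it against the
brute-force definition and an independent implementation. DEGs are the
genes with adjusted p < α (default 0.05), split by fold-change sign.

## IFN annotation, enrichment and score

Interferon-regulated genes are consumed as a flat symbol list (matching is
case-insensitive); the packaged list is a synthetic stand-in assembled
from the packaged DEG table's own flags plus the score panel, and any
production use should supply a curated list. Enrichment of IFN membership
in up- vs down-regulated DEGs uses the two-sided Fisher exact test with
the minimum-likelihood rule (sum of hypergeometric outcomes no more
probable than the observed table) — the convention of the cited analysis
environment — not the doubled one-sided p.

The IFN score standardizes each panel gene (*IFI27, IFI44L, IFIT1, ISG15,
RSAD2, SIGLEC1*) against the control group: z_gi = (x_gi − μ_g)/σ_g with
μ_g, σ_g the control mean and sample SD, then sums over genes,
S_i = Σ_g z_gi. Two consequences are exact by construction and are
asserted as invariants: the control mean of S is 0, and the control SD of
each gene's score row is 1. The expression scale feeding the score is
log2(normalized + 1) by default (configurable to linear); the choice is
recorded in the result object. Group comparisons use Welch's unpaired
two-sided t-test by default, with the pooled-variance Student variant
available for sensitivity analysis.

## Preranked GSEA

Genes are ranked by r = sign(log2FC)·(−log10 p) (p = 0 is clamped to the
smallest positive float with a warning; ties break by gene id for
reproducibility). The enrichment score is the classic weighted
Kolmogorov–Smirnov running sum with weight 1: hits add |r|^w normalized by
the in-set sum, misses subtract 1/(N − |set|), and ES is the extremum of
largest magnitude. The null permutes gene labels — equivalently, assigns
the set to uniformly random positions — because the preranked stage
receives only a ranked list, never the sample-level data needed for
phenotype permutation. The permutation p-value is
(1 + #{same-sign |ES*| ≥ |ES|})/(1 + #same-sign), NES divides ES by the
mean same-sign permuted |ES|, and FDR across sets is BH. Everything is
driven by one seed; identical seeds give bit-identical results. Sets
smaller than `min_size` (default 5) after intersection are skipped with a
log entry. Permuted ES values are computed vectorized from sorted hit
positions (candidate extrema occur only immediately before and at hits),
which keeps 200 sets × 1000 permutations on a 1000-gene list under a few
seconds.

## PCA and OPLS-DA

PCA is SVD on column-centered data with a deterministic sign convention
(largest-|loading| element positive); it is used for outlier screening of
samples. OPLS-DA follows the Trygg–Wold NIPALS scheme for a single binary
response: per iteration the predictive weight w ∝ Xᵀy is computed, the
loading's y-orthogonal component defines an orthogonal weight, and X is
deflated by that orthogonal component; after `n_ortho` deflations (default
1, the standard two-class display) one predictive component is regressed.
Orthogonal score vectors are exactly orthogonal to the predictive score by
construction and this is asserted to 1e-8 on every fit. Features are
autoscaled (unit variance) before fitting, the discriminant-analysis
default of the cited package; constant features are dropped with a
warning. Q² is estimated by stratified 7-fold cross-validation with a
fixed fold seed; with random labels the median Q² is negative, which the
tests use as the null check. With `n_ortho=0` the model reduces exactly to
one-component NIPALS PLS, which is cross-checked against an independent
PLS implementation in the tests. The OPLS feature set defaults to the
DEGs (the displayed analysis of the emulated study names exactly those);
a flag switches to all genes.

## Subgroup discovery

The emulated study annotated its seven-patient "high inflammatory subset"
by visual inspection of the clustered heatmap. `identify_high_subset`
fixes a testable surrogate: cluster patient samples on the z-scored
upregulated DEGs (Euclidean distance, complete linkage, matching the
heatmap convention), cut at k = 2, and take the higher-mean cluster. The
call is only reported as "distinct" when the cluster means differ by at
least 0.75 z-units. That threshold was calibrated against the generator
itself: with no planted subset the k = 2 cluster-mean difference stays
below ≈ 0.6 z (40 null seeds), while a planted amplified subset produces
≈ 0.94–1.1 z — all-sample z-scoring compresses the gap, so a 1.0 cutoff
would sit inside the signal distribution. 0.75 is the midpoint of the two
measured distributions and separates them cleanly; with it, the rule
recovers the planted subset essentially always and calls no subset on
null data. Ties and degenerate cuts (a single cluster, or a high cluster
smaller than `min_size`) yield "not distinct" with an empty subset.

Clinical comparisons between subset and remaining patients (FM-score, FSS
total) use Welch's t-test and report group means ± sample SDs.

## NPX protein panel

NPX values are consumed as given (the vendor normalization is out of
scope). Ingestion pivots the Olink-style long CSV (SampleID, Assay,
UniProt, NPX) and rejects duplicate sample×assay measurements. Per-protein
differences are Welch two-sided t-tests with BH across the panel;
proteins constant in both groups get p = 1 with a warning. The z-score
heatmap matrix and the protein-high sample subset reuse the expression
z-scoring and the subgroup rule above; the subset's FM-score and FSS
totals are then compared against the remaining patients.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions the analysis is validated under.

- **Counts**: baseline means are log-normal(meanlog 3, sdlog 1.5),
  reproducing the heavy right tail of base means (~9–3800) in the
  reference DEG table; counts are NB with a single common dispersion
  φ = 0.085 (the value reported for the emulated cohort); per-sample size
  factors are log-normal(0, 0.25) so normalization is non-trivial.
- **Planted signal**: 33 up- and 27 down-regulated genes with |log2FC| ~
  N(1.0, 0.5) clipped at 0.1; 25/33 of the upregulated genes are labelled
  IFN-regulated and six of those carry the score-panel symbols (their
  baselines floored at 50 counts so control SDs are stable). A further 5%
  of non-DE genes are labelled IFN-regulated as annotation background.
- **Subset**: 7 of the 25 patients form the high-inflammatory subset; their
  planted log2 fold changes are multiplied by `subset_amplification`
  (default 2.0). An optional shared latent factor (`subset_corr_sd`,
  default 0) induces within-subset correlation of the up-genes; the
  emulated study does not characterize that correlation, so it is a knob
  rather than an asserted value.
- **Clinical**: patient WPI ~ round N(13.3, 2.0), SSS ~ round N(7.9, 1.5)
  (FM-score ≈ 21 ± 2.5, the diagnosed range), subset patients get an
  expected FM-score excess of 2.5 split 60/40 across WPI/SSS; controls sit
  near zero pain scores with low fatigue. Clipping to the legal ranges
  biases the planted shift by < 0.1.
- **NPX**: 92 proteins, baselines N(5, 2) spanning the reference table's
  NPX range, per-sample noise SD 0.5 log2 units (a realistic
  inter-individual spread for such panels), 19 proteins shifted by
  N(0.9, 0.15) clipped at 0.1 — Table-scale shifts at the upper end, so
  that panel-wide FDR recovery is a sharp test — amplified in subset
  samples by the same factor as the counts.

Determinism: counts, clinical and NPX draw from independent streams seeded
as (seed, 0/1/2), so each output is bit-reproducible regardless of which
others are generated.

What the generator does **not** emulate: batch effects and site
confounding, gene–gene correlation outside the planted subset factor,
per-gene dispersion variation (a single φ is used, as a single value is
all the emulated study reports), count outliers, protein LOD censoring,
and missingness. Passing recovery tests therefore demonstrate correctness
of the statistical machinery under the assumed model, not robustness to
real-data artefacts.

## Problem sizes and tolerances

Simulation-based tests and the acceptance script run the cohort at 2,000
genes (the generator's default stays at 19,000 to mirror the emulated
cohort); at that size every per-seed quantity they measure is already
stable, and a 100-seed sweep completes in seconds. Floating-point
invariants that hold by construction (control score mean, BH vs brute
force, ES vs prefix sums) are asserted at 1e-9–1e-12; orthogonality of
OPLS scores at 1e-8; Monte-Carlo quantities at ~3 standard errors of the
replicate count used.

## Known limitations

- The NB Wald test uses a normal reference; at much smaller group sizes
  than the default cohort it will be anti-conservative (the calibration
  band is only verified at the study's n).
- The two-cluster subset rule assumes at most one elevated subgroup;
  multiple subgroups would be merged or missed.
- The GSEA null is gene-label permutation; inter-gene correlation is not
  preserved, as is inherent to preranked mode.
- OPLS-DA is limited to two classes and reports no VIP/S-plot variable
  selection.
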