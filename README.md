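# ifnsig

Interferon-signature and inflammation analysis for two-group bulk RNA-seq
cohorts with a matched Olink-style serum protein panel.

Fibromyalgia (FM) and related pain syndromes have been linked to immune
activation: B-cell transcriptomes of patients show coordinated upregulation
of interferon-stimulated genes, and sera show elevated inflammatory
proteins. `ifnsig` packages that analysis as a tested, reusable pipeline
for case/control studies of this design (here: FM patients vs healthy
controls, labelled `FM`/`CTL`):

- **Differential expression** on gene-level counts: genes with zero reads
  in more than five samples are filtered out, libraries are normalized by
  median-of-ratios size factors (s_j = median_g k_gj / (∏_j' k_gj')^{1/n}),
  and each gene is tested with a negative-binomial Wald test
  (var = μ + φμ², moment dispersion shrunk toward a baseMean trend),
  with Benjamini–Hochberg FDR control.
- **IFN annotation and enrichment**: DEGs are flagged against a supplied
  interferon-regulated gene list and the up- vs down-regulated contrast is
  tested with a two-sided Fisher exact test.
- **IFN score**: for the six-gene panel *IFI27, IFI44L, IFIT1, ISG15,
  RSAD2, SIGLEC1*, each gene is standardized against the control group,
  z_gi = (x_gi − μ_g)/σ_g, and S_i = Σ_g z_gi is compared between groups
  with an unpaired two-sided t-test. By construction the control mean of
  S is exactly 0.
- **Preranked GSEA** with the ranking metric r = sign(log2FC)·(−log10 p),
  the weighted Kolmogorov–Smirnov running-sum enrichment score, a
  gene-label permutation null, NES and FDR.
- **Ordination**: PCA for outlier screening and OPLS-DA
  (Trygg–Wold NIPALS, 1 predictive + n orthogonal components, R²Y and
  7-fold cross-validated Q²) for class separation.
- **Subgroup discovery**: complete-linkage Euclidean clustering of patient
  samples on z-scored upregulated DEGs, with a reproducible rule for
  calling a "high inflammatory subset", plus Welch comparisons of clinical
  scores (FM-score = WPI + SSS, range 0–31; FSS item sum, range 9–63).
- **NPX protein panel**: per-protein Welch t-tests on log2-scale NPX
  values with BH FDR, z-score heatmap matrices, and clinical comparison of
  the protein-high subset.
- **Synthetic cohorts**: a generator that reproduces the statistical
  structure of such a study (negative-binomial counts with planted fold
  changes, an amplified patient subset, clinical scores, a shifted protein
  panel) together with the planted ground truth, for power and calibration
  testing.

## Worked example

```python
from ifnsig import SimConfig, simulate_cohort
from ifnsig.expression import filter_low_expressed, normalize
from ifnsig.diffexpr import nb_wald_test, classify_degs
from ifnsig.ifn import (annotate_ifn, compute_ifn_score,
                        compare_ifn_scores, fisher_ifn_enrichment)

cohort = simulate_cohort(SimConfig(n_genes=2000, seed=1))
counts, truth = cohort["counts"], cohort["truth"]
filtered = filter_low_expressed(counts)        # zero counts in > 5 samples
log_norm = normalize(filtered, scale="log2")

de = nb_wald_test(filtered)
up, down = classify_degs(de, alpha=0.05)
print(f"{len(up)} genes up, {len(down)} down at FDR < 0.05")

ann = annotate_ifn(de, truth.ifn_genes)
up_ifn = int(ann.loc[sorted(up), "ifn_regulated"].sum())
down_ifn = int(ann.loc[sorted(down), "ifn_regulated"].sum())
_, p = fisher_ifn_enrichment(len(up), up_ifn, len(down), down_ifn)
print(f"IFN-regulated among upregulated: {up_ifn}/{len(up)} (Fisher p = {p:.2g})")

ctl = filtered.samples_in_group("CTL")
fm = filtered.samples_in_group("FM")
panel = compute_ifn_score(log_norm.values, ctl, truth.panel_genes)
t, df, pval = compare_ifn_scores(panel.ifn_score, fm, ctl)
print(f"IFN score: CTL {panel.ifn_score[ctl].mean():.1f} +/- "
      f"{panel.ifn_score[ctl].std(ddof=1):.1f}, "
      f"FM {panel.ifn_score[fm].mean():.1f} +/- "
      f"{panel.ifn_score[fm].std(ddof=1):.1f}, p = {pval:.2g}")
```

prints

```
30 genes up, 17 down at FDR < 0.05
IFN-regulated among upregulated: 22/30 (Fisher p = 4e-07)
IFN score: CTL 0.0 +/- 1.8, FM 17.3 +/- 6.7, p = 7.6e-13
```

The synthetic cohort (23 controls, 25 patients, 7-sample high-inflammatory
subset) plants 33 up- and 27 down-regulated genes; at 2,000 genes the Wald
test recovers most of them, the planted IFN-regulated genes dominate the
upregulated set, and the six-gene score separates the groups while
averaging exactly zero in controls.

A command-line interface mirrors the library:

```bash
ifnsig simulate --out cohort/ --seed 1          # synthetic cohort + truth
ifnsig de --counts cohort/counts.tsv --clinical cohort/clinical.csv --out de.tsv
ifnsig fixtures                                 # packaged reference tables
```

`ifnsig run --config cfg.yaml` executes every stage and writes TSV tables
plus a machine-readable `report.json`, byte-identical for a fixed config
and seed.

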