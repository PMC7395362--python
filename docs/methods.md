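# Methods

## The analysis in brief

The package classifies bulk RNA-seq profiles of histologically normal
breast tissue into an *Active* and an *Inactive* transcriptome phenotype
and quantifies the association of the Active state with an
adipocyte-rich, metabolically activated tissue composition. The pipeline
has five computational stages: (1) within-batch phenotyping by
hierarchical clustering on variably expressed classifier genes, (2)
sign-corrected signature scoring, (3) per-gene quantile-normalisation
batch integration, (4) filtering of RNA-expressed cancer-gene hotspot
variant calls with per-sample burden statistics, and (5) group-comparison
and correlation statistics over donor/histology covariates, plus
post-processing of gene-set enrichment reports.

## Phenotyping model and assumptions

Expression enters as a non-negative TPM matrix with one batch label per
sample. Genes are transformed to log2(TPM+1) and median-centred per gene;
when batches are analysed independently the median is taken within batch,
since each batch is phenotyped separately and the centring should not mix
processing chemistries. Classifier genes are gated on variability:
interquartile range of the centred values strictly greater than 0.8 (the
shipped default), with the IQR computed by linear interpolation between
order statistics. The quantile rule is exposed in the API because the
size of the selected panel is sensitive to it.

Samples are clustered by agglomerative hierarchical clustering with
distance 1 − Pearson correlation between sample profiles and average
linkage, the standard pairing for transcriptome heat-map clustering; both
metric and linkage are configurable. The dendrogram is cut into exactly
two clusters. Samples are sorted canonically before linkage so the
bipartition cannot depend on column order. Degenerate inputs
(all-identical profiles, a cut that fails to produce two groups) raise
errors rather than returning arbitrary partitions.

Labelling is decided by the classifier signature score

    S_s = [ Σ_{g∈U} log2(T_g+1) − Σ_{g∈D} log2(T_g+1) ] / (|U| + |D|),

with U the Active-upregulated and D the Inactive-upregulated genes. The
cluster with the higher mean score is Active. Signature genes absent from
the matrix are dropped from both the sums and the denominator, keeping
the score a mean over observed genes; treating absent genes as zero
expression would conflate platform absence with biological
non-expression. An exactly tied pair of cluster means raises an error
demanding an explicit policy — a silent tie-break would make labels
irreproducible. For signatures with no down component a `mean_log2_up`
method (plain mean of log2(TPM+1) over the gene list) is provided.

Differential expression between labelled groups uses a per-gene
two-sided Wilcoxon rank-sum test with Benjamini–Hochberg adjustment and
reports genes at adjusted p < 0.05. BH is the specific FDR procedure
chosen; constant genes are assigned p = 1 rather than excluded.

## Batch integration

Integration is pairwise: one target batch (by convention the larger,
formalin-fixed "F" batch) and one source batch. For each gene
separately, zeros are removed from both vectors; the empirical quantiles
of the zero-excluded source and target are evaluated on a probability
grid of length min(n_source_nonzero, n_target_nonzero) — resolution is
limited by the smaller vector, and the grid length is configurable — and
the source values are transformed by monotone linear interpolation
between the paired anchors. Zeros are reattached at their original
positions as exact zeros. Values outside the anchor range clamp to the
extreme target anchors rather than extrapolating, which keeps TPM
non-negative. Tied source values collapse to a single anchor (the map is
a function of value, not rank position). A gene with no nonzero values on
either side cannot be mapped; it is carried unchanged and recorded in the
diagnostics table. Mapping operates on the TPM scale, where "zero
expression" is well defined; a monotone transform of TPM gives the same
ranks either way.

Consequences that are tested as invariants: the zero set is unchanged,
the map is monotone, integrating twice is a no-op to float precision, and
the target batch is returned bit-identical.

## Hotspot-variant filtering

A call survives only if all of the following hold, every bound inclusive:
likelihood score ≥ 5, 0.02 ≤ AF ≤ 0.40, AD ≥ 2, predicted non-silent
amino-acid change, and presence in **every** supplied hotspot list
(intersection of the MSK-IMPACT-style and GTEx-expressed-style lists).
The likelihood score is treated as an opaque numeric input from the
variant caller. Silence is derived from the consequence string by a
keyword table (missense/nonsense/stop/frameshift/splice/inframe count as
protein-altering); strings with no protein-altering keyword are
conservatively classed as silent, so only affirmatively annotated calls
pass. Hotspot membership prefers the (gene, amino-acid change) key and
falls back to (gene, contig, position, ref, alt), because amino-acid
hotspot lists and position-oriented lists key their entries differently.
Per-sample burden is the surviving-call count (zero for samples with no
calls) and its covariate association uses Spearman rank correlation on
pairwise-complete records; a constant burden returns an explicit NaN.

## Enrichment post-processing and association statistics

GSEA itself (permutation NES machinery) is consumed, not implemented: the
module reads report tables. Adipose-associated set names contain "fat",
"adip" or "lip" (case-insensitive) and none of the exclusion terms
("sulfate", "sulfation" by default — the exclusion list is extensible
because sulfation pathways match "lip" spuriously). Enrichment is
summarised at FDR q ≤ 0.10 with fractions reported to one decimal
percent, and a hypergeometric upper-tail probability is provided as a
convenience over-representation statistic.

Group comparisons report per-group n/mean/median/SD with the test that
was actually run: Wilcoxon rank-sum for grouped continuous measures
(exact null distribution for small tie-free groups, tie-corrected normal
approximation otherwise), Welch t for mean differences of continuous
variables, chi-square (no continuity correction) for proportions. The
correlation matrix is pairwise-complete Pearson or Spearman with
p-values from the exact t distribution of r and flags at p < 0.05 (*)
and p < 0.01 (**); no multiple-testing correction is applied by default
(a BH option exists) because the flags mirror raw-p reporting
conventions. Constant variables yield flagged NaN entries, never silent
drops. Missing covariate cells (e.g. risk scores that cannot be computed
for donors under 35) are carried as NaN and removed pairwise.

## Synthetic cohort generator

The generator's defaults define the study conditions used throughout the
tests and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| cohort | 96 "F" + 55 "P" samples | the two processing batches, so unequal-batch quantile mapping is exercised |
| Active fraction | 47/96 (F), 31/55 (P) | observed per-batch phenotype rates |
| genes | 50 up + 50 down signature, 900 background | enough background for variance decomposition at low cost |
| effect size δ | 2 log2 units | clear two-state separation in log2 TPM |
| batch distortion | per-gene affine in log2 space, scale U(0.7, 1.3), shift U(−1, 1), on batch P | monotone by construction, so quantile mapping can in principle remove it exactly — the correction stage has a verifiable target |
| zero inflation | 5% (F), 10% (P) | batch-specific dropout, exercising zero-exclusion/reattachment |
| composition | Dirichlet (12, 1.5, 1.5) Active vs (7.5, 3.75, 3.75) Inactive | Active mean ≈ 78% adipocyte nuclei vs ≈ 50%, a ≈ 1.6-fold difference with halved stromal/epithelial shares |
| Gail 5-year score | mean 1.46 (Active) vs 1.18 (Inactive), SD 0.5; missing under age 35 | the phenotype-linked risk shift and the structurally missing scores |
| variant burden | Poisson, rate 0.5 + 5.0 × adipocyte fraction | mean ≈ 3.7 passing calls/sample and a built-in positive burden–adipocyte correlation |
| AF, AD | Beta(2, 28) truncated to the passing window; AD = max(2, Poisson(6)) | low-frequency expressed variants with internally consistent depths |

Expression is drawn per gene as Gaussian in log2 space (baseline mean
U(1, 6), SD U(0.5, 0.9)), shifted by ±δ in Active samples for
up/down-signature genes, back-transformed to TPM and zero-inflated. The
variant table mixes ground-truth-passing calls drawn from a fixed hotspot
catalogue with calls that each violate exactly one filter criterion; a
separate fixture generator additionally plants boundary records at
likelihood = 5, AF = 0.02, AF = 0.40 and AD = 2 to pin the inclusive
bounds. A synthetic GSEA-style report generator gives adipose-named sets
a higher enrichment probability so the post-processing stage has
structured input. All draws come from one `numpy` Generator seeded from
the spec, so outputs are bit-reproducible.

What the generator does **not** emulate: real gene identifiers and
co-expression structure (genes are independent given phenotype and
batch), count-level sequencing noise, library-size artefacts, germline
contamination of variant calls, correlated covariate noise, and any
single-cell structure. Passing tests therefore demonstrate correctness
of the algorithms under the assumed generative structure, not
performance on real cohorts; on real data the clustering-dependent
quantities (classifier panel size, per-batch phenotype counts) remain
sensitive to metric/linkage and quantile-rule choices, which is why all
three are configurable and recorded in run provenance.

## Numerical and design choices

- IQR gate is strict (`>`), matching the stated threshold semantics.
- Quantile grids use numpy's linear interpolation between order
  statistics everywhere, so the mapping and the variable-gene gate share
  one quantile convention.
- Correlation-distance matrices treat constant profiles as maximally
  distant (distance 2) from all others; an all-constant matrix is an
  error.
- Wilcoxon switches between the exact and the tie-corrected asymptotic
  null automatically (scipy's policy); the exact branch is validated
  against full enumeration for group sizes ≤ 6 in the test suite.
- The pipeline's problem sizes (1000 genes, 151 samples, 10–20 replicate
  seeds) were chosen as the smallest cohorts at which the planted
  structure is comfortably detectable; all stages run in seconds at these
  sizes.
- The pipeline orchestrator validates configuration (threshold ranges,
  AF bound ordering) before any computation and embeds the seed and a
  hash of the analysis parameters in every output header.

## Known limitations

- Integration is strictly pairwise (two batches); multi-batch
  harmonisation and empirical-Bayes correction are out of scope.
- No single-sample classifier: phenotyping requires a cohort to cluster,
  and both labels must occur within each batch or the run is flagged
  degenerate.
- Gene identifiers are matched by exact, case-sensitive string equality;
  no alias resolution is attempted.
- The reported group-comparison p-values are per-variable; cross-variable
  multiplicity is intentionally left to the reader unless the BH option
  is enabled.
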