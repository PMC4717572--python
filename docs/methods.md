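# Methods

This note documents the models, parameter choices, numerical details and
known limitations of the `netwas` package. It is written for users who want
to understand what the pipeline computes and what its tests do and do not
demonstrate.

## Phase I: gene-based association scoring

**Model.** For each gene, SNPs within a symmetric window (default
`window_bp = 50 000`; strand is stored but ignored) are collected, and the
gene statistic is the sum of the per-SNP 1-df chi-square quantiles,
*T* = Σ χ²₁⁻¹(1 − pᵢ). Two-sided t-test p-values from the association stage
are treated directly as chi-square(1) tail probabilities — the standard
large-sample equivalence (t² → χ²₁); at small n this is an approximation.

**Null.** Under no association but arbitrary LD, the vector of SNP z-scores
is approximately MVN(0, **R**) with **R** the dosage correlation matrix, so
the null of *T* is simulated by drawing **z** ~ MVN(0, **R**) (via Cholesky
of the repaired **R**; if exact semidefiniteness defeats the factorization,
a diagonal jitter of 1e-10, escalated ×10 up to three times, is added) and
summing zᵢ². The p-value is the add-one estimator (r + 1)/(n + 1): slightly
conservative, never exactly zero, so downstream −log₁₀ transforms are safe.

**Adaptive simulation effort.** Stages of 10³, 10⁴ and 10⁵ cumulative
simulations (configurable); scoring escalates to the next stage while the
current estimate is below 10/stage. This bounds the relative Monte Carlo
error of small p-values at roughly 30 % of the estimate or better while
clearly null genes stop after 10³ draws. Each gene draws from its own child
seed, so per-gene results are reproducible in isolation.

**LD estimation and PSD repair.** **R** is the Pearson correlation of
dosage columns; monomorphic SNPs are dropped with a warning. Sampling noise
or user-provided matrices can make **R** indefinite, so eigenvalues are
clipped at zero and the matrix rescaled to unit diagonal; the magnitude of
the largest clipped eigenvalue is recorded on the result and logged
(tolerance 1e-8 before repair counts as clean). On generated data at
n ≥ 500 the repair is a near-no-op (< 1e-6), which the tests assert.

**Degenerate inputs.** Genes with no assigned SNPs are reported as
unscored — never silently given p = 1 — and excluded from phase II labels.
P-values below the smallest positive double are clamped with a warning
rather than mapped to an infinite statistic.

**Multi-mapping diagnostic.** One SNP may fall in the windows of several
genes; a cluster of mutually overlapping genes can therefore all inherit
significance from the same variants (the protocadherin-alpha failure mode).
The diagnostic links every SNP below `alpha_snp` (default 5e-4) to its
assigned genes and reports connected components with ≥ 2 genes together
with the shared SNPs, making the confound machine-readable instead of a
Manhattan-plot observation.

## Phase II: network re-prioritization

**Classifier.** A linear soft-margin SVM (default cost 1.0) on the rows of
the network weight matrix. Linear is the conventional choice for this
method and keeps the model auditable — the test suite checks the decision
values against an independent dual quadratic-program solve. The libsvm
convergence tolerance is tightened to 1e-6 because decision values feed a
ranking. Class imbalance (positives are typically 1–5 % of genes) is
handled by inverse-frequency class weighting; without it the SVM
degenerates to the majority class. Network weights already live in [0, 1]
with a shared meaning across genes, so no feature scaling is applied.

**Cross-validation and scoring.** Labeled genes are split into five random
folds (re-drawn up to ten times if a training set would see one class, then
stratified). Each labeled gene receives the decision value of the one model
that did not train on it — scoring training genes with their own model
would leak their labels into the ranking. Unlabeled genes are scored by the
mean over the five fold models. Ranks (1 = most disease-like) follow
descending decision value with lexicographic tie-break, so a run is fully
deterministic given its child seed.

**Aggregation.** Iterations differ only in the fold partition; each gene's
ranks are summed and the ascending summed-rank order (tie-break by gene id)
is the final prioritization. When every run covers the same genes — always
true here — the mean-rank order is identical; both statistics are written
to `combined-results.csv`.

**Permutation null.** The gene-to-p-value assignment is shuffled
(preserving the p-value multiset, hence the positive count) and a single
NetWAS run performed per permutation; the distribution of the resulting
AUCs is the reference for how much ranking performance the network alone
provides.

**Isolated genes.** A network is rejected only if it has no edges at all.
Individual all-zero rows are legitimate in sparse networks (they occur at
the default background density) and are scored by the SVM bias alone.

## Evaluation

AUC is the Mann–Whitney U statistic with mid-rank tie correction, i.e.
P(score_pos > score_neg) + ½P(tie), computed over the intersection of the
gold-standard universe and the ranked genes; empty positive or negative
sets raise instead of silently returning 0.5. Every method is evaluated on
one common universe (network ∩ scored genes) so AUC differences reflect
ranking quality, not coverage. Uncertainty is a percentile bootstrap
(default 1000 replicates) resampling genes with their labels attached;
single-class replicates are redrawn and counted. The permutation band is
the percentile bootstrap CI for the mean AUC over permuted-label runs. The
inflation factor is λ = median(χ²₁⁻¹(1 − p)) / median(χ²₁), with the
chi-square median computed by quantile inversion at run time rather than
hard-coded as 0.456.

## Synthetic data

The generator emulates the data features the methods actually consume:

- **Genotypes.** One LD block per gene. Per haplotype copy, SNPs share a
  latent Gaussian factor with loading √ρ (`ld_rho`, default 0.5), and an
  allele is carried when the latent value falls below the allele-frequency
  quantile (frequencies uniform in [0.05, 0.5]); dosage is the sum of two
  copies. This gives tunable within-gene LD and exact {0,1,2} dosages
  without coalescent machinery — adequate because downstream stages consume
  only p-values and correlation matrices.
- **Phenotype.** Four independent standard-normal covariates (age-, sex-,
  education- and intracranial-volume-like) with fixed coefficients
  (1.0, −0.5, 0.25, 0.8), plus `effect_size` (default 0.5 SD per allele)
  times the dosage of one tagged SNP per disease gene, plus unit normal
  noise. The fixed covariate effects mean the association stage demonstrably
  must adjust for them; one tagged SNP per gene keeps gene-level power
  interpretable.
- **Gene models.** Genes are spaced ≥ 2×window apart so windows of distinct
  genes are disjoint, except for an optional cluster of mutually
  overlapping genes (staggered 2 kb starts, 40 kb spans) used to exercise
  the multi-mapping diagnostic.
- **Network.** All pairs of disease-module genes are connected at
  `module_edge_weight` (default 0.8); background edges appear with
  probability `background_edge_density` (default 0.02) and weight uniform
  in (0, module_edge_weight/2).
- **Benchmark.** `generate_netwas_benchmark` fixes the re-prioritization
  study design: 1000 genes, a 50-gene module, 40 % of module genes given
  gene p < 0.01 (log-uniform down to 1e-5), all other genes uniform p, gold
  standard = the module.

Defaults (800 subjects, 500 genes) are desk-scale study conditions: cohort
size matches the mid-hundreds neuroimaging-genetics setting, while gene
count keeps a full pipeline run under a couple of minutes. No published
effect sizes exist for this endophenotype's loci, so `effect_size` is
chosen for testability, not realism.

**What the generator does not emulate:** realistic human LD maps and
allele-frequency spectra, imputation artifacts, population structure or
relatedness, genotype missingness, and real functional-network topology
(degree distributions, overlapping pathways). Passing tests therefore
demonstrate correctness and calibration of the algorithms under controlled
conditions, not performance on real cohorts.

## Known limitations

- **The permuted-label null is not centered at 0.5 when the gold standard
  is itself one coherent network module.** Module genes have strongly
  correlated feature rows, so each permuted-label SVM moves the whole
  module as a block: up when enough module genes land among the permuted
  positives, down otherwise. With balanced class weighting the tipping
  point sits at the hypergeometric mean of that count, which exceeds its
  median, so downward moves are more likely and the per-run AUC
  distribution is bimodal with a mean below 0.5 (≈ 0.36 at the benchmark
  defaults, as the acceptance suite measures). An external gold standard
  that does not coincide with a single tight module does not have this
  geometry. The benchmark keeps the band because it remains a valid — and
  conservative — reference for the signal-recovery comparison; its mean
  should not be read as an unbiased chance level.
- Gene p-values from the t-to-chi-square equivalence are approximate at
  small cohort sizes.
- The sum-of-chi-squares statistic weights all SNPs equally; top-fraction
  variants and long-range (3D-chromatin) SNP-gene assignment are out of
  scope.
- Bootstrap intervals are percentile (not BCa); with AUC near 1 they
  collapse and undercover.
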