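# Methods

This note records the statistical procedures `sarcsig` implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, the numerical conventions, and the design choices made where the
underlying analysis recipe was genuinely open.

## Study design being modeled

The pipeline targets a blood-transcriptome severity study: three phenotype
classes — healthy controls (HC), uncomplicated sarcoidosis (US), and
complicated sarcoidosis (CS: cardiac, neurologic, or FVC < 50% pulmonary
involvement) — sampled in two populations (African American, European
American).  Differential expression is run per population for the CS-vs-HC
contrast; the union of the per-population gene lists forms the analysis set
on which signature discovery runs with all pooled samples; the discovered
signature is then evaluated on several contrasts (all sarcoidosis vs HC,
CS vs US, per-population) and corroborated by pathway enrichment and by
case-control association of SNPs in signature-gene regions.

## SAM differential expression

For a two-group split with n₁, n₂ samples, gene g gets

    d_g = (x̄₂ − x̄₁) / (s_g + s₀),
    s_g = √[(1/n₁ + 1/n₂)(SS₁ + SS₂)/(n₁ + n₂ − 2)],

the pooled-SE moderated statistic; at s₀ = 0 it is exactly the
equal-variance two-sample t (a tested invariant).  s₀ is selected by the
standard recipe: candidates are the 0th–100th percentiles (step 5) of the
s_g distribution, and the winner minimizes the coefficient of variation of
median |d| across quantile bins of s_g (bin count n_genes/25 clipped to
[2, 100]).  Below 100 genes the recipe is unstable and s₀ = median(s_g) is
used with a warning.

The null is a label-permutation ensemble (default 200 rounds, same s₀
throughout).  When the number of distinct label arrangements C(n, n₂) is at
most the requested count, the enumeration is exhaustive; each arrangement
runs through the same code path as the observed statistic, so exhaustive
mode is bitwise-reproducible against direct recomputation.

q-values: for the threshold at |d_g| the estimated FDR is
π₀ · E_p[#{null |d| ≥ |d_g|}] / #{observed |d| ≥ |d_g|}, with
π₀ = min(1, 2·fraction of observed d inside the pooled-null IQR) and q_g
the minimum FDR over all thresholds at which g is called (hence monotone
non-increasing in |d|; |d| ties break by gene input order).  Two
deliberate choices:

* **Mean, not median, null exceedance counts by default.**  The median
  count collapses to zero in the extreme tail, which hands the top gene
  q = 0 in roughly half of pure-null datasets (measured: P(any selection)
  ≈ 0.49 over 100 null cohorts).  The mean count is the expected number of
  falsely called genes and keeps the procedure calibrated (measured ≈ 0.06,
  within Monte-Carlo noise of the nominal 0.05).  `exceedance_mode="median"`
  remains available.
* **π₀ = 1** is available as a conservative option (`pi0_mode="one"`).

Selection rule: q < 0.05 **and** max(FC, 1/FC) > 1.4, both strict, where
FC = 2^(case log2 mean − control log2 mean) is the ratio of geometric
means.  The symmetric fold-change reading is forced: down-regulated genes
(FC < 1) are reported as differential throughout the field's tables, so a
one-sided "FC > 1.4" cannot be meant literally.

## Signature discovery

* Linear soft-margin SVM (libsvm via scikit-learn), cost C = 1 by default
  (the underlying analyses do not state it); tolerance 1e-8 so that exact
  symmetries (label flip ⇒ w negation) hold to ~1e-9.
* Genes are standardized before training.  Inside cross-validation the
  z-score parameters are computed on the training folds only and frozen for
  the held-out fold — no leakage through the scaler.  The RFE ranking
  itself, however, is computed on all pooled samples, mirroring the
  original design; its per-round CV accuracies are therefore optimistically
  biased for small gene counts, which is why `nested_rfe` evaluation mode
  exists (see below).
* Elimination schedule: drop ⌈0.1·n⌉ lowest-w² genes per round, one gene
  at a time once ≤ 50 remain; w² ties break by input gene order.  This
  balances a fine accuracy-versus-size curve near the interesting region
  against runtime.
* Parsimony: the smallest round whose mean CV accuracy ≥ A* − SE*, where
  A* is the best round's mean and SE* its standard error over the round's
  CV repetitions (one-SE rule).  With B repetitions per round the SE is
  sd/√B; if every repetition is identical the SE is 0 and the rule
  degenerates to "smallest round attaining the maximum".
* Signature weights: single-run RFE gives only binary membership, so the
  reported per-gene weight is a selection frequency — the fraction of
  stratified bootstrap reruns (default 100) in which the gene survives to
  the signature size.  Reported genes are sorted by non-increasing weight.

## Evaluation

* Repeated stratified k-fold CV, default 1,000 × 5.  The per-repetition
  metric pools the k folds' confusion counts into one accuracy /
  sensitivity / specificity triple (stable for small folds, rather than
  averaging per-fold ratios).  Sensitivity = TP/(TP+FN) with the disease
  class positive.
* `fixed_signature` mode retrains classifier weights in every training
  split but never re-selects genes; `nested_rfe` re-runs the elimination
  inside each split for an honest error estimate.  Fixed-signature is the
  default used for headline-style numbers.
* Signature comparison: Welch (unequal-variance) t-test on the accuracy
  distributions; if both are degenerate (zero variance) p is defined as 1
  for equal means, else 0, with a warning.
* Label permutation (`permute_labels=True`) draws a fresh permutation per
  repetition — the chance-level reference.
* PCA: top-2 axes of the gene-standardized signature submatrix; sign fixed
  by making each axis's largest-magnitude loading positive.
* Cross-cohort transfer: cohorts are matched by gene symbol (case
  sensitive; multi-probe symbols collapsed upstream to the
  highest-mean-expression row) and standardized independently — across
  platforms only within-cohort relative expression is comparable.
  Signature genes missing from the test cohort are dropped with a warning;
  fewer than half present is an error.

## Enrichment

Upper-tail hypergeometric P(X ≥ overlap) with the universe equal to the
analysis set (genes surviving QC and the sex-chromosome filter); each
pathway set is intersected with the universe first, and sets that do not
intersect it are skipped with a note.  Only over-representation is tested.
Benjamini–Hochberg step-up adjustment (via statsmodels) at 0.05.  The exact
hypergeometric is a documented simplification of annotation-tool variants
(e.g. EASE-adjusted Fisher scores), whose databases are out of scope.

## SNP association

Allele-count (allelic) test: a = case minor-allele count, b = case major,
c/d likewise for controls, totals 2× the sample counts.  1-df Pearson
chi-square without continuity correction; Fisher's exact test when any
expected cell < 5; monomorphic SNPs get p = 1, OR = 1, flagged.
OR = ad/bc with +0.5 added to all cells when any cell is zero
(Haldane–Anscombe).  The allelic test is a documented stand-in: severity
GWAS reports rarely state trend-vs-allelic-vs-logistic choices or
covariates, so printed P/OR values from real cohorts are not reproduction
targets.  No multiple-testing correction at this stage (nominal P < 0.01
convention); BH adjustment is available separately.  SNP-to-gene mapping:
inside the gene span → intron (exon structure not modeled), within 10 kb
before the start → upstream, within 10 kb past the end → downstream,
nearest gene wins ties; strand is not modeled.

## Synthetic-data generator

The expression generator states this world: gene-level log2 expression,
baselines ~ N(7, 1.5²) across genes, i.i.d. Gaussian log2 noise per
measurement (default SD 0.5), a planted signature whose class means step
baseline → baseline ± δ (US) → baseline ± 2δ (CS) with 90% of signature
genes down-regulated (matching the observed dominance of down-regulation
in severe disease), and optional per-population per-gene baseline shifts
~ N(0, pop_shift_sd²).  δ defaults to 1.0 log2 units — inside the
fold-change range such studies report (≈0.42–2.17 linear), not a fixed
literature quantity.  The severity pattern is encoded multiplicatively
(CS effect = 2δ) as a qualitative additive-model emulation.

Deliberately not emulated: gene–gene correlation, heavier-tailed or
intensity-dependent noise, batch effects, probe-level artifacts, linkage
disequilibrium, admixture.  A green test on this world therefore
establishes algorithmic correctness and calibration under clean
assumptions, not robustness to real microarray pathology.

One consequence worth stating plainly: at the generator's default effect
sizes a 2δ = 2-log2-unit shift against 0.5 noise is a 4σ separation per
gene, so cross-validated accuracy saturates at 1.0 long before the planted
signature size is reached, and the one-SE rule then bottoms out at 1–4
genes rather than ~20.  Recovering the full planted set at the planted
size is a property of the elimination path (the planted genes survive to
the size-20 round), not of the parsimony rule, in this regime.  Real
cohorts, with per-gene effects well under 1σ, sit in the regime where the
accuracy curve bends near the true signature size.

Genotypes: control allele frequency p₀ (planted or uniform on [0.1, 0.5]),
case frequency p₁ = OR·p₀/(1 − p₀ + OR·p₀), dosages ~ Binomial(2, p)
(Hardy–Weinberg within groups).

## Reproducibility

All randomness flows through `numpy.random.default_rng`.  The pipeline
derives per-stage substreams from the global seed and the stage name
(`seed·1000003 + crc32(stage) mod 2³¹`), so toggling one stage never
perturbs another's draws.  Rerunning a config reproduces every output file
byte-for-byte; the manifest records input checksums, stage seeds, and
output hashes.

## Known limitations

* Probe summarization, batch correction, and missing-value handling are
  out of scope; matrices must be complete (permutation machinery assumes
  complete data) and gene identity is the symbol string.
* The RFE accuracy trace is optimistically biased (selection sees all
  samples); use `nested_rfe` for honest generalization error.
* The chi-square/Fisher switch at expected-cell 5 is a convention; near
  the boundary the two give slightly different p-values.
* Population structure is modeled only as baseline shifts; no
  effect-size × population interaction by default (an optional multiplier
  exists for testing discordance).
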