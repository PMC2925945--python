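# Methods

## Array substrate and quality control

The pipeline consumes exported *average beta* values (methylated /
total signal, a proportion in [0, 1]) for ~1.5k promoter CpG loci per
sample, with a matching detection p-value for every measurement.  QC is
applied in a fixed order: samples are dropped when strictly more than
75% of their loci have detection p > 1e-5; loci are then dropped when
their median detection p across the retained samples exceeds 0.05 (even
counts use the mean of the central pair); finally X/Y loci are removed.
Running the sample filter first makes the locus medians well defined on
the retained cohort.  Filters never alter retained values — outputs are
submatrices of the input.

## Locus-wise quasi-binomial screen

Average beta values are overdispersed proportions, so each locus is
modelled as quasi-binomial: logit link, binomial variance function, and a
free scale parameter estimated by Pearson chi-square / (n − 2).  With a
single binary covariate (invasive vs non-invasive) the fit is saturated:
fitted group means equal observed group means, and the slope is exactly
logit(mean_invasive) − logit(mean_non-invasive).  The whole screen is
therefore computed in closed form and vectorised across loci; an
independent IRLS implementation serves as the test oracle.  The p-value
uses a two-sided t reference with n − 2 degrees of freedom (the standard
quasi-likelihood convention).  Beta values are clamped to
[1e-6, 1 − 1e-6] before the logit; loci with zero residual variation are
flagged degenerate and reported conservatively (slope 0, p 1 when the
group means agree).

Multiplicity is handled with Storey q-values: π0 is estimated on the
λ-grid 0.05…0.95 (step 0.05) with a cubic polynomial smoother evaluated
at λ = 0.95 and clipped to (0, 1]; for fewer than 100 p-values the
smoother is unreliable and π0 = 1 is used, which reduces the procedure
exactly to Benjamini–Hochberg (also available explicitly via `pi0=1`).

Hierarchical clustering (Manhattan metric, average linkage) is provided
as the exploratory companion view.

## Random-forest screen

Invasive status is classified from the beta profiles by a bagged
ensemble of regression trees on y ∈ {0, 1} with a per-split random
feature subspace of size m (mtry).  Keeping the response numeric lets
one ensemble supply both the misclassification OOB error (averaged OOB
prediction thresholded at 0.5, ties counting half an error so the rate
is invariant to class relabeling) and MSE-based permutation importance.
The tree learner is scikit-learn's `DecisionTreeRegressor`; bootstrap
and OOB bookkeeping are handled in the package so per-tree OOB indices
are available.

* **mtry tuning** — the grid is [⌈√M/2⌉, ⌊2√M⌋] (optionally thinned to a
  fixed number of evenly spaced values); the m with the lowest OOB error
  wins, ties toward the smallest m.  At M = 1413 loci the grid is
  19…75.
* **Permutation test** — the observed OOB error is referred to the OOB
  errors of forests grown on label-permuted data (default 100
  permutations, reusing the tuned m), with
  p = (1 + #{null ≤ observed}) / (1 + n_perm).
* **Importance** — per tree, the OOB MSE is recomputed with one locus's
  OOB values shuffled; per-tree baseline and permuted MSEs are averaged
  over the forest *before* taking the ratio (stable when individual
  trees have zero OOB error), and importance is the percent increase of
  mean OOB MSE.  Selection uses a strict cut, default 6% (5% is the
  within-screen reporting alternative; both are config).
* n_trees defaults to 500 for standalone screens and 200 inside the
  pipeline — the tuning curve and importances are stable at these sizes
  for the cohort scales the package targets.

## Recursively partitioned beta-mixture model

Methylation profiles are clustered by recursively fitting 2-class
mixtures of beta distributions (loci independent given class).  The EM
M-step solves the weighted beta maximum-likelihood equations per locus
by a damped Newton iteration on the digamma equations, initialised at
weighted method-of-moments, with shape parameters floored at 1e-3.  EM
is initialised from a seeded split of the samples at the weighted median
of their first principal-direction scores of the logit-beta matrix, and
iterates until the relative log-likelihood change falls below 1e-6 (cap
1000 sweeps); the log-likelihood trace is retained and checked
nondecreasing.

A node is split iff the 2-class BIC improves on the 1-class BIC, with
the effective sample size (sum of fractional weights reaching the node)
in the BIC's log term.  Recursion passes responsibility-weighted (soft)
sample weights rather than hard assignments, matching the
empirical-Bayes character of the procedure; nodes with fewer than 8
effective samples are not considered for splitting.  A sample's
posterior over leaves is the product of branch responsibilities along
its path (rows sum to 1); hard classes are the argmax.

Class–phenotype association uses the Pearson chi-square statistic on the
class × phenotype table referred to a label-permutation null (default
10,000 permutations), p = (1 + #{null ≥ observed}) / (1 + B).

### Class-vs-rest AUC

For locus j and leaf k, the other leaves' fitted betas are pooled with
prevalence weights and approximated by a moment-matched normal G_jk,
truncated to [0, 1] and renormalised.  AUC_jk = P(X_k > X_other) is the
integral of the class-k beta survival function against G_jk, evaluated
by the trapezoid rule on a uniform 10,001-point grid, and folded to
max(AUC, 1 − AUC) (the ROC is taken on whichever side dominates).  The
integral agrees with a 10⁶-draw Monte-Carlo estimate to < 0.005.  Two
thresholds are exposed: 0.90 for within-model locus ranking and 0.75 for
the intersection rule.

## Candidate selection

Within each series, a locus passes if q < 0.05 (GLM), importance > 6%
(forest), and AUC > 0.75 for the *class of interest* — the leaf with the
highest (soft) prevalence of invasive tumors, resolving per series.
Candidates are the loci passing all three screens in every series.
Selection is evaluated per series before intersecting (never on pooled
data), is symmetric in series order, and is monotone: tightening any
threshold never adds candidates.

## Validation statistics

Pyrosequencing data are percent methylation (0–100) per sample, gene and
CpG site.  Site agreement uses Spearman correlation; per-gene summaries
average the observed sites (missing sites are averaged over, with the
contributing-site count reported).  Grade/stage contrasts use the
tie-corrected Kruskal–Wallis test and a *protected* two-sided Wilcoxon
rank-sum (only run when the protecting Kruskal–Wallis p is below α):
exact by exhaustive enumeration when min(n) ≤ 8, otherwise a
tie-corrected normal approximation with continuity correction.  Tumor
grade is contrasted as low (1–2) vs high (3), the coding used by all the
reported results; the alternative (1 vs 2–4) remains available by
recoding the sheet.

Methylation exposures are dichotomised at the median of the analysed
series (≤ median = negative).  2×2 tables give cross-product odds ratios
with Woolf log-scale 95% CIs and a 0.5 continuity correction iff a cell
is zero.  Multivariable logistic models (ML by Newton/IRLS, tolerance
1e-8, max 100 iterations, Wald CIs) adjust for age, gender, and TP53 IHC
intensity; perfect separation is detected and raised rather than
reported.  A single-binary-exposure logistic fit reproduces the 2×2
cross-product OR exactly (saturated equivalence, tested to 1e-6).  The
additive exposure is the indicator of above-median methylation at all
three validated genes.  A sensitivity refit adds a tumor-cell-percentage
covariate and reports coefficient deltas, flagging collinearity.  qPCR
fold changes use the Pfaffl efficiency-corrected ratio
E_target^ΔCt(target) / E_ref^ΔCt(ref).

Printed-table percentages are reproduced with round-half-even, the
rounding consistent with the published tables' cells.

## Synthetic cohorts

`CohortConfig`/`generate_cohort` draw per-locus beta values from
Beta(a_jk, b_jk) with latent sample classes; parameters can be given
explicitly per class and locus, or compactly as per-locus baseline means
(default: a bimodal promoter-like mixture, mostly unmethylated) plus a
precision (a + b, default 20).  Invasive status is Bernoulli per sample
(optionally class-dependent), and a configurable set of differential
loci has its mean shifted (upward for positive shifts) in invasive
samples only.  Detection p-values are Uniform(0, 1e-6) for passing
measurements and Uniform(1e-5, 1) for failures at a configurable
per-sample rate, matching the QC thresholds' operating points.
Covariates emulate the cohort structure: age ~ N(63, 9.5²) (+2 years if
invasive), 75% male, and TP53-high drawn with a configurable odds ratio
(default 7) given invasive status so confounder adjustment can be
exercised.  Array loci are generated independently given class; real
arrays carry residual inter-locus correlation beyond class structure, so
passing tests bound behaviour under the model's assumptions, not under
arbitrary dependence.

The two-series discovery scenario (`two_series_configs`, 80 + 150
samples, 300 loci, precision 15) mirrors the structure of the real
cohorts: a latent hypermethylator class (40% prevalence) shifts a broad
40% of loci upward by 0.22 and is strongly enriched for invasive tumors
(invasive fraction 0.85 vs 0.08), reproducing the general invasive
hypermethylation and driving the mixture split; five spiked loci are
shifted 0.2 → 0.6 by invasive status directly in both series.  Under
this design the class loci pass the GLM and AUC screens but carry little
forest importance, noise loci pass nothing, and the spiked loci alone
survive the intersection — the behaviour the selection strategy is
designed to produce.

Pyrosequencing tables use a Gaussian copula per gene: sites share an
equicorrelated latent normal whose Pearson correlation is
2·sin(π·ρ_s/6), so the realised between-site *Spearman* correlation
matches the configured ρ_s; marginals are group mean + noise·z truncated
to [0, 100] (exactly the group means when noise is zero).

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; the pipeline derives
per-stage seeds from one master seed through `numpy.random.SeedSequence`
in a fixed order.  The test suite and the acceptance script run the
stochastic checks at desk scale — null calibration on 150 × 500 cohorts,
recovery on 80/150 × 300 two-series cohorts, 4-class recovery at 240 ×
100, coverage at 100–200 replicates of n = 300 — sizes at which the
checked properties are stable while a full run stays in the minutes
range.

## Known limitations

* The BIC split criterion uses the plain 2-class vs 1-class comparison
  with effective sample size; other variants of the split criterion
  would shift the discovered class number on borderline data.
* The class-vs-rest AUC inherits the optimism of model-based separation
  measures: fitted leaf distributions are sharpened by the same data
  that defined the leaves.
* The quasi-binomial screen models per-sample beta with no covariates,
  matching the array-stage analysis; covariate-adjusted array models are
  out of scope.
* Wald intervals and the Woolf CI are first-order; profile or exact
  intervals are not provided.
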