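# Methods

This note records the statistical conventions, default parameters, and
design choices behind `stromasig`, and what the synthetic generators do
and do not emulate.

## Differential expression and signatures

Expression is assumed to arrive as normalized log2 intensities;
normalization itself (e.g. RMA for Affymetrix arrays) is out of scope.
The two-group test is Welch's t (unequal variances) on the log2 values;
`log2_fc` is the difference of group means, and genes constant across
the pooled samples are assigned p = 1 (no evidence). Moderated
empirical-Bayes tests would give different tail behavior with few
replicates; results derived at n = 5 per group should be read with that
in mind.

Signatures keep genes with |log2_fc| > `min_abs_log2_fc` AND
NLP > `min_nlp`, both strict inequalities (thresholds are printed with
">", so ties at the boundary are excluded). "Fold change > 4" on the
linear scale corresponds to `min_abs_log2_fc = 2`. A p ≤ 0.05 style
threshold maps to NLP ≥ 1.30103, implemented as
`min_nlp = -log10(0.05) - 1e-9` so boundary-exact p-values pass.
Direction is the sign of the fold change in the reference comparison.

## Cross-species projection and filtering

Ortholog tables are user-supplied two-column files; live database
lookups are out of scope. A source gene with several listed orthologs
keeps the first listed target (every drop is logged); genes without a
mapping, or whose target is absent from an optional platform universe,
are dropped. Variance filtering keeps genes whose unbiased (n−1)
variance across all samples exceeds the cutoff (default 0.5, strict).
Unbiased variance is used everywhere in the package.

## Separation test

The contrast the test formalizes: does this signature separate tumor
from normal stroma better than random gene sets of the same size?

* Per-sample statistic: the matrix is row-standardized (zero-variance
  rows dropped); a sample's score is the mean of its signature-gene
  z-values, signed +1 for "up" genes and −1 for "down" genes. The
  per-sample summary is a package choice — oriented mean z-scoring is
  standard signature-scoring practice.
* Observed statistic: one-sided Wilcoxon (Mann–Whitney) U of tumor
  scores vs normal scores, tumor expected higher ("up" means higher in
  the tumor-context reference); a `flip` flag reverses the
  orientation.
* Null: `n_perm` (default 10,000) signatures of the same size drawn
  uniformly without replacement from the full gene universe of the
  matrix (not the variance-filtered subset), with direction labels
  permuted from the observed signature. Resampling gene *lists* (not
  sample labels) is the implemented reading; it asks specifically
  whether the identity of the genes matters.
* p-value: add-one estimator (n_ge + 1)/(n_perm + 1), never zero.

The Wilcoxon helper uses mid-ranks for ties; the one-sided p is exact
(full enumeration) for tie-free pooled samples of size ≤ 12 and a
normal approximation with tie and continuity correction otherwise.

PCA export projects samples on the first two principal components of
the standardized signature submatrix; each component's sign is fixed by
making its loading on the alphabetically first gene non-negative, so
coordinates are reproducible across eigensolvers.

## Preranked enrichment

Classic weighted KS running sum with exponent 1: at set members the sum
rises by |metric| normalized over the set's total, at non-members it
falls by 1/(N − n_set); ES is the signed extremum (first occurrence on
ties). The null re-draws each set uniformly from the ranked universe
(`n_perm` default 1,000). NES divides ES by the mean magnitude of
same-sign null scores (the GSEA v2 convention); the nominal p counts
same-sign null scores at least as extreme, with the add-one rule over
all `n_perm` draws. Because opposite-sign nulls enter the denominator
but not the numerator, the null distribution of this p concentrates
below ~0.5 rather than being uniform; its small-p tail is what the
calibration tests check. The ranking metric (`log2_fc` or signed NLP)
is a declared input, not inferred. The leading edge is the set members
at or before the peak (at or after, for negative ES).

## Ridge Cox and the prognostic index

The penalized objective is ℓ(β) − (λ/2)‖β‖², with ℓ the Cox log
partial likelihood under the Breslow tie convention (Efron ties are not
implemented). Covariates are standardized internally (training
parameters are reused for test rows). Newton iterations with
step-halving; convergence when the penalized gradient max-norm falls
below 1e-8, capped at 100 iterations. λ = 0 recovers the unpenalized
MLE; at β = 0 with a single binary covariate the score test reproduces
the log-rank statistic (verified numerically in the tests).

λ selection, when not fixed by the user, maximizes the k-fold (default
5) cross-validated partial likelihood in the full-minus-fold form
ℓ_all(β_train) − ℓ_train(β_train) over a logarithmic grid from 0.01 to
100 (9 points).

The prognostic index of patient i is Σ_g β_g x_ig, always computed
out-of-fold: per repeat, a random k-fold partition (default k = 10);
each fold scored by a model trained on the rest; final PI is the
arithmetic mean over repeats (default 10) — the mean is a package
choice, the repeats exist to decouple the result from one particular
partition. Risk groups split at the 50th percentile of all PIs (linear
interpolation); "high" is strictly above the threshold, ties fall to
low risk.

Kaplan–Meier curves use the product-limit estimator with
censored-at-event-time patients counted at risk; the log-rank test is
the standard two-group O−E/V form with hypergeometric variance and a
1-df chi-square reference.

A caveat worth stating: a log-rank test applied to groups derived from
cross-validated risk scores of the *same* cohort is mildly
anti-conservative, because a patient's group label depends on other
patients' outcomes through the trained coefficients. On simulated null
cohorts (n = 200, 30 noise genes) the empirical rejection rate at
α = 0.05 is near 10% rather than 5%. The p-value should be read as a
descriptive index of separation, as is common for this design; a fully
calibrated test would require an outer permutation of outcomes.

## Synthetic generators

* **Stroma cohort**: background log2 values i.i.d. Gaussian(7,
  noise_sd) — the location and spread resemble normalized oligo-array
  data; defaults are 1,000 genes, 49 tumor vs 52 normal samples, and a
  planted 38-gene signature (16 up / 22 down) shifted by ±effect_size
  (default 1.0 SD) in the tumor group, mirroring the shape of a
  laser-capture breast-stroma comparison.
* **Four-genotype fibroblast study**: two paired control-vs-knockout
  comparisons (normal and tumor context), 2,000 genes, 5 samples per
  genotype, noise SD 0.3, planted |log2 FC| 3.0; planted lists default
  to 107 tumor-context and 22 normal-context genes sharing exactly 4,
  the printed sizes of the reference design.
* **Survival cohort**: genes i.i.d. standard normal; event times from a
  proportional-hazards model with exponential baseline (Weibull via a
  shape parameter); independent exponential censoring whose rate is
  solved numerically against the realized event times so the expected
  censored fraction matches the request (default 0.3, a typical breast
  cancer follow-up censoring level).

What the generators do *not* emulate: probe-level effects, batch
structure, correlated gene blocks beyond the planted signature,
non-proportional hazards, or informative censoring. Passing tests
demonstrate the algorithms recover planted structure under these
idealized conditions; they do not certify performance on real arrays.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses: full-size planted-list recovery for the
two study arms (107/22/4 and 69/15/1); the default stroma cohort at
10,000 permutations; 200 null cohorts at 500 permutations and 100
power cohorts at 1,000 permutations for the separation test; 2,000
null genes for Welch calibration; 1,000 simulations for log-rank
calibration; 100 cohorts for ridge sign recovery; and 50 cohorts each
(signal and null, n = 200, 10×10-fold CV, λ = 1) for the end-to-end
prognostic readout. These sizes keep the full run to a few minutes on
one CPU while leaving Monte-Carlo error well inside the tolerances the
tests assert.

## Known limitations

* Welch's t rather than a moderated test makes small-n DE gene counts
  noisy; signature sizes from 5-per-group designs vary across reruns.
* Breslow ties only; heavy tie structure (coarsely discretized times)
  will bias coefficients slightly relative to Efron handling.
* The separation test's gene-list null keeps the sample correlation
  structure fixed; it does not test against sample-label exchange.
* Dense matrices only; missing values must be imputed upstream.
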