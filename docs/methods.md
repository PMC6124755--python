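# Methods

## The problem

Classical morphometric "stress markers" in rodents — adrenal hypertrophy,
thymus involution, reduced body-weight gain, elevated glucocorticoids — are
individually unreliable discriminators of chronic stress. `stresspair`
implements a bivariate alternative: an exhaustive **top-scoring-pair (TSP)**
search over a panel of physiological and immunological parameters, which
finds the pair of parameters whose *within-sample ordering* best separates
stressed from non-stressed animals, together with a kernel-SVM comparison
model and the resampling machinery needed to attach significance and
uncertainty to the blinded-set prediction error.

## The TSP model

For a parameter pair (i, j) and class c, let

    p_c = P( x_i < x_j | class c ),

estimated as the fraction of class-c samples with the ith value strictly
below the jth. The pair score is Δ = |p₁ − p₂|; the fitted classifier is
the fixed rule *y = x* in the (i, j) plane: a sample is assigned the
**orientation** class (the class with the larger p_c at fit time) iff
x_i ≤ x_j. Properties and conventions:

* **Exhaustive search.** All p(p−1)/2 unordered pairs are scored; ties in Δ
  are broken by a secondary score γ (the absolute between-class difference
  of the mean within-sample rank gap rank_j − rank_i, computed over the full
  parameter ranking of each sample), then lexicographically. γ is a
  reconstruction of the classical rank tie-break; the exact secondary score
  of historical TSP implementations is not uniquely documented, so γ is
  implementation-defined here and only matters for equal-Δ pairs.
* **Ties in values** (x_i = x_j) count as NOT(x_i < x_j) during scoring
  (strict inequality) and go to the orientation class at prediction — two
  fixed, documented rules.
* **Raw units.** Unlike expression data, the parameters carry heterogeneous
  physical units, and the comparison x_i < x_j is applied to raw recorded
  values. A pair can only score if the two parameters' numeric ranges cross
  between classes (e.g. left adrenal weight in mg against relative thymus
  weight in mg/g, both of magnitude ~1–4). No normalization is inserted;
  this mirrors the source analysis and is stated prominently because it is
  the method's main caveat outside rank-comparable data.
* **Invariances.** Δ and all predictions are invariant under any strictly
  increasing transform applied jointly to both paired features, and under
  adding a common constant; these are property-tested.
* k-TSP voting (majority over the k best pairs) is deliberately out of
  scope; only the single top pair is modeled.

## The SVM comparison model

A soft-margin C-SVC with Laplacian kernel k(x, y) = exp(−σ‖x − y‖)
(Euclidean norm, k(x, x) = 1) on the two selected features. Defaults:
C = 1; σ by the median heuristic (reciprocal of the median pairwise
distance in the standardized training set); features standardized with the
training-set mean/SD (the kernel-toolchain convention); stratified 10-fold
cross-validation with a seeded shuffle for the internal CV error, reusing
the full-training-set scaler and σ. The dual problem is solved by
scikit-learn's SMO to tolerance 1e-6; the contract is the converged
solution, not the solver, and tests cross-check decision values against a
generic QP solution of the same dual on a small instance. Hyperparameters
are intentionally not searched.

## Resampling inference

* **Monte Carlo null** (default N = 10000): each iteration replaces every
  validation sample's two feature values by independent uniform draws within
  that feature's observed [min, max], pooled over both classes, keeps the
  actual labels, and records the frozen model's misclassified fraction.
  With n₁/n₂ labels the expected null error is (n₁(1−q) + n₂q)/n for the
  random ordering probability q, hence ≈ 0.5 for near-balanced sets — the
  chance-level anchor. One could instead resample from a pre-generated pool
  of uniform values; both readings converge to the same null mean, and the
  per-sample-uniform reading is the one implemented.
* **Empirical p-value**: p = (r + 1)/(N + 1) with r the number of null
  draws with *strictly* lower error than observed; p is exact, monotone in
  r, and floored at 1/(N + 1) (no zero p-values).
* **Bootstrap** (default R = 10000): validation rows are resampled with
  replacement, the model frozen (per-sample misclassification indicators are
  computed once, so replicate errors are exact resampled means). The 95%
  interval is Efron's BCa: z₀ = Φ⁻¹(#{replicates < observed}/R)
  (proportions 0 or 1 are clamped half a replicate inside, logged), and the
  acceleration a from the jackknife skewness of leave-one-out errors;
  adjusted percentile bounds are read from the replicate distribution with
  linear-interpolation quantiles. An all-identical replicate set yields a
  degenerate point interval, logged. Tests cross-check against
  `scipy.stats.bootstrap(method="BCa")`.
* One root seed spawns independent substreams (via `SeedSequence`) for the
  cohort, the SVM folds, each null and each bootstrap, so every stage is
  individually reproducible.

## PCA

Computed on centered, unit-SD parameters (i.e. the correlation structure)
via SVD of the standardized matrix; min(n − 1, p) components. Eigenvector
signs are arbitrary, so a fixed convention (largest-magnitude loading of
each component positive) keeps exports stable. The biplot export gives
PC1/PC2 arrow coordinates per feature plus a PC3 magnitude bin on a 1–5
scale (equal-width bins of |loading| from 0 to the maximum). Variance
ratios sum to one over the retained components (the correlation matrix has
rank ≤ n − 1); agreement with an independent eigendecomposition of the
correlation matrix is asserted to 1e-8.

## The synthetic cohort generator

Real deposited measurements cannot be redistributed here, so the generator
is a first-class module that reproduces the *statistical structure* the
analysis assumes, not any particular dataset:

* **Panel**: 28 named parameters with unit suffixes — adrenal weights
  (left/right/total, absolute and body-weight-relative), pituitary, spleen,
  thymus (absolute and relative), plasma corticosterone, mesenteric
  lymph-node cell counts, splenocyte-viability ODs across a corticosterone
  dose ladder (basal and LPS-stimulated), body weight day 1/day 20 and the
  gained weight. Relative weights are exactly absolute/day-20 body weight,
  total adrenal exactly left + right, gain exactly day 20 − day 1, so the
  absolute/relative correlation families arise by construction.
* **Classes**: primaries are truncated-at-zero Gaussians (positivity plus
  approximate normality of morphometrics). The stressed class carries mean
  shifts in control-SD units — left adrenal +2.0, right adrenal +0.8
  (weaker, reflecting the laterality of the trophic response), thymus −1.5,
  spleen +0.8 — and all its SDs inflated by `noise_sd_ratio` (default 1.5),
  modelling the higher heterogeneity of stressed animals. Left/right
  adrenal and each viability ladder share one latent factor per block.
* **Design sizes**: 47 animals per class; per class the last 19 (control) /
  18 (stressed) are tagged `validation`, giving the 57-train / 37-blinded
  design the analysis is sized for. Other `n_per_class` values default to a
  40% validation fraction.
* **Calibration**: baselines (means/SDs) were chosen once, from typical
  adult male C57BL/6 physiology, such that (a) the planted pair's ranges
  cross the y = x boundary the way informative raw-unit pairs must, and (b)
  no uninformative pair family (e.g. total adrenal vs body-weight gain)
  crosses competitively — the generator's contract includes recovering the
  planted pair in ≥ 95% of cohorts at n_per_class = 30, which the defaults
  meet with margin (top Δ ≈ 0.62 vs ≈ 0.35 for the best competitor).
* **What "no signal" means**: zeroing the shifts alone leaves the
  dispersion ratio, and unequal dispersion *is* rank signal (measurably
  above-chance accuracy). The chance-level property therefore holds when
  both the shifts are zero and `noise_sd_ratio` = 1, and that is how the
  tests state it.
* **Not modelled**: measurement missingness, batch effects, dose–response
  kinetics of the viability assays, any attempt to match a real dataset's
  exact means or covariances. Passing tests on these cohorts show the
  machinery is correct and well-calibrated under the assumed structure; they
  do not certify performance numbers on real animals.

With the default effect sizes the blinded-set TSP accuracy is typically
78–95% across seeds (the dispersion inflation caps per-class separability
near z ≈ 1), the Monte Carlo null mean is 0.500 ± 0.005, and the planted
pair is recovered essentially always at the 57-animal training size.

## Problem sizes and numerics

Tests and the acceptance script use the design sizes throughout — 57/37
cohorts, N = 10000 null iterations, R = 10000 bootstrap replicates, 100
cohorts for the recovery rate — which run in a few seconds on one CPU
thanks to batched prediction (null draws are predicted in one call and
reshaped) and indicator-based bootstrap replicates. Degenerate inputs are
rejected by name: zero-variance features (PCA, SVM scaling), min = max
feature ranges (null), single-class labels, derived-column shift requests,
unknown split tags.

## Known limitations

* Raw-unit comparison restricts informative pairs to parameters whose
  numeric ranges cross; the package warns (rather than fails) when every
  pair scores zero.
* γ is implementation-defined (see above); rankings of equal-Δ pairs may
  differ from other TSP implementations.
* The SVM's CV error depends on the unstated historical fold count and
  hyperparameters; C = 1, median-heuristic σ and 10 folds are declared
  defaults, not a claimed reconstruction.
* `.xls` spreadsheets (as opposed to `.xlsx`) are not readable; convert to
  `.xlsx` or delimited text first.
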