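# Methods

## Model

`mvtlogit` fits a Bayesian multivariate latent Student-*t* regression for a
vector of p = 4 correlated binary outcomes per subject — here the
cardiometabolic late effects obesity (O), insulin resistance (I),
(pre-)hypertension (H) and dyslipidemia (D) in survivors of childhood acute
lymphoblastic leukemia.  Each subject i has a latent vector

Z_i ~ St_p(mu_i, delta² R, nu),    Y_i^j = 1(Z_i^j > 0),

with linear predictors mu_i^j = beta_0^j + beta_1^j T1_i + beta_2^j T2_i +
beta_C^j' C_i, where T1/T2 are dummies for the second and third levels of a
three-category combined corticosteroid/cranial-radiotherapy exposure
(baseline: low dose / no CRT) and C_i are the adjustment covariates (sex,
age at diagnosis, WBC count at diagnosis, time since diagnosis).  R is an
unstructured correlation matrix capturing residual outcome dependence.

The scale constant delta² = pi²(nu−2)/(3 nu) with nu = 7.3 calibrates the
t margin to the standard logistic distribution (maximum CDF gap < 0.002,
checked by `logistic_approx_gap`), so every non-intercept coefficient reads
as a conditional log odds ratio exactly as in a univariate logistic model.
nu is a fixed constant, configurable for sensitivity checks but never
estimated.

Priors: beta^j ~ N(0, diag(1000, 4, …, 4)) independently per outcome
(variance 4 keeps the bulk of each log-OR prior within ±3.9; the large
intercept variance is only weakly informative), and R uniform over the
space of valid correlation matrices.

## Posterior computation

The t distribution is represented as a normal scale mixture with
per-subject gamma mixing variables phi_i ~ Gamma(nu/2, rate nu/2), giving a
data-augmented MCMC with sweep order phi → Z → beta → R:

* phi_i | rest ~ Gamma((nu+p)/2, rate (nu+q_i)/2) with
  q_i = (z_i − mu_i)'(delta² R)⁻¹(z_i − mu_i);
* Z updated one coordinate at a time from univariate truncated-normal full
  conditionals, truncated to (0, ∞) if y = 1 and (−∞, 0] otherwise.  Draws
  use an exact inverse-CDF with `log_ndtr`/`ndtri_exp`, which stays finite
  and correctly distributed arbitrarily far into the tails (no rejection
  step to fail there);
* the stacked coefficient vector (outcome-major: beta = (beta^O, beta^I,
  beta^H, beta^D)) from its exact multivariate-normal full conditional with
  posterior precision P_prior + delta⁻² R⁻¹ ⊗ Σ_i phi_i x_i x_i';
* R by random-walk Metropolis on the 6 free off-diagonals with an isotropic
  normal proposal; proposals outside the correlation space count as
  rejections and the uniform prior cancels in the ratio.  The proposal
  scale is adapted by Robbins–Monro toward 25% acceptance during burn-in
  only and frozen afterwards, preserving the Markov property of retained
  draws.  A zero proposal scale freezes R (recorded as accepted by
  convention in the run metadata).

The default schedule is 1,050,000 iterations, 50,000 burn-in, thinning 100
(10,000 retained draws, applied to all parameters); `REDUCED_SCHEDULE`
(20,000 / 2,000 / 10) is the desk-scale preset used by the CLI.  Retained
draws are stored streaming, so the full schedule needs memory for 10,000
rows only.  One seeded generator drives the whole chain; identical seed,
config and data reproduce the retained draws bit-identically.

Sampler validity is established three ways in the test suite: a
successive-conditional (prior-invariance) simulation on a tiny two-outcome
model, equivalence of posterior means with an independently coded
univariate latent-t sampler in the single-outcome case, and replicate-fit
coverage of generator ground truth.

## Orthant probabilities

Joint outcome-configuration probabilities are orthant integrals of the
multivariate t.  These are computed by a randomized quasi-Monte-Carlo
routine of the Genz separation-of-variables type: the first scrambled-Sobol'
coordinate drives the chi mixing variable, the remaining p−1 coordinates the
sequential conditional-normal construction.  Defaults: 2048 points × 8
scrambled randomizations, target absolute error 5×10⁻⁴ (3-sigma across
randomizations), point count doubled up to twice if the target is missed,
then an error is raised carrying the achieved estimate.  The seed of the
Sobol' stream is fixed per call (overridable), so repeated evaluations are
identical.  Observed accuracy on 4-dimensional orthants is ~10⁻⁵–10⁻⁴,
verified against `scipy.stats.multivariate_t.cdf` and plain Monte Carlo
with 10⁶ draws.  A `relaxed()` preset (256 × 3, no error check) serves
inner loops over posterior draws, where ~10⁻³ integration noise is far
below posterior spread.  `configuration_probabilities` evaluates all 2^p
configurations for a whole cohort in a single batched call (one Cholesky,
one Sobol' stream) — without this batching the cumulative contrasts are
impractically slow, which mirrors the computational bottleneck reported for
the original analysis.

Semi-infinite limits are ±inf sentinels throughout; configurations are
enumerated lexicographically with the first outcome as the most significant
bit.

## Association measures

For every retained draw: conditional ORs exp(increment·beta) (WBC reported
per 10 × 10⁹/L); population risk differences by g-computation — each
survivor's marginal probability F_nu(mu^j/delta) under arm T_l minus under
T_0 at observed covariates, averaged over all n survivors; configuration
contrasts as orthant-probability differences averaged the same way; and
cumulative contrasts P(N ≥ k) obtained by summing configuration contrasts
over patterns with at least k positive outcomes (k = 3 sums exactly the
five 3-or-4-positive patterns).  Summaries are the empirical posterior
mean, median and equal-tailed 95% credible interval (2.5/97.5 percentiles
with linear interpolation); the median is the headline OR point estimate
because OR posteriors are right-skewed.  Per-draw identities — the 16
configuration contrasts sum to 0, the k = 1 contrast equals minus the
all-zero configuration's, and each marginal PRD equals the sum of its 8
configuration contrasts — are enforced in tests at twice the integrator
tolerance.

## Data handling

Cumulative corticosteroid dose (prednisone-equivalent, mg/m²) is
dichotomized at the third quartile, 13,414 mg/m²; doses exactly at the
threshold count as low (the source analysis states a third-quartile split
without an equality rule; ties-to-low is this package's convention).
High-dose without CRT does not occur in the design and is rejected.
Analysis is complete-case: rows missing the exposure ingredients are
dropped with a logged count.  Covariates enter on their natural scale; the
WBC functional form (identity, log, sqrt — each 1 df) is chosen by smallest
AIC among maximum-likelihood univariate logistic fits of insulin resistance
on the fully adjusted design, ties broken by the fixed candidate order and
failed fits (e.g., perfect separation) excluded with a warning.

## Synthetic cohort generator

Because the study's individual-level data are not public, the generator
produces cohorts with the same structure and known ground truth:

* sex ~ Bernoulli(0.49); age at diagnosis ~ gamma moment-matched to mean
  6.59 / SD 4.59 years; time since diagnosis ~ N(15.4, 5.1²) truncated at
  the 5-year inclusion minimum; WBC ~ lognormal with median 9.60 × 10⁹/L
  and log-SD set by the mean/median ratio (mean 30.2), clipped to the
  observed range 0.42–361.  The lognormal family is a modeling choice
  justified by the strong right skew (median ≪ mean); only the summary
  statistics are constrained by data.
* exposure by a proportional-odds-style latent score 0.15·age +
  1.0·log(WBC) + logistic noise, with cutpoints at the score's empirical
  41/75% quantiles — marginal proportions hit the 41/34/25% targets at any
  n while the score induces the observed confounding (CRT groups older,
  higher WBC).  WBC enters the score on the log scale; on the natural scale
  its heavy tail would dominate assignment.  Setting both score
  coefficients to zero is the no-confounding control.
* outcomes from the latent mechanism itself (gamma mixing, correlated
  normal noise, sign thresholding).  Treatment and covariate log-ORs and R
  default to the reported adjusted estimates (dyslipidemia LD/CRT log 1.98,
  rho_OI = 0.69, rho_OD = 0.36, …) — these are generator inputs, not
  validation targets.  Intercepts are calibrated by 1-D root finding on an
  internal 20,000-subject reference sample so marginal prevalences equal
  31.5/17.0/12.0/40.2%.
* group-conditional CS doses (normal, clipped to the correct side of the
  threshold) make generated cohorts round-trip through the ingestion layer.

What the generator does **not** emulate: raw biomarkers underlying the
binary outcomes, covariate interdependence beyond the exposure score (only
margins and group contrasts are constrained), and any measurement error.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the model, not robustness to real-data misspecification.

## Numerical and design choices

* Truncated-normal sign invariants are re-asserted after every sweep;
  boundary ties go to the closed side (y = 0 ⇔ Z ≤ 0).
* Geweke diagnostic uses window fractions 0.1/0.5 with long-run variances
  from Geyer's initial-monotone-sequence estimator; ESS uses the same
  estimator, capped at the chain length.  Both are invariant to affine
  rescaling.
* Sequential five-number summaries split the chain into 10 equal contiguous
  segments (remainder dropped), matching the sequential-boxplot visual
  check.
* The analysis pipeline treats the with/without-WBC sensitivity analysis as
  first-class model variants (crude, adjusted_full, adjusted_no_wbc);
  cumulative contrasts are produced for the adjusted variants by default
  (crude by flag).
* Configuration-level measures in the pipeline run on a systematic
  subsample of retained draws (default 200) with the relaxed integrator;
  ORs, PRDs and correlation summaries always use every retained draw.

## Problem sizes used in the shipped checks

Replicate recovery runs use n = 400 cohorts with a 12,000/3,000/4 schedule
— sized so the slow-mixing correlation chains reach ESS ≈ 50+, which the
credible-interval endpoints need — and the per-parameter coverage band is
the 3-sigma binomial band around 0.95 for the replicate count actually run.
The acceptance script fits one n = 241 synthetic cohort with the same
schedule and evaluates cumulative contrasts on 60 systematically chosen
draws.  Monte-Carlo oracles use 10⁶ draws.  These sizes are desk-scale
choices; the published schedule remains the package default.

## Known limitations

* Single-chain workflow (no R-hat across chains), matching the original
  analysis design.
* nu fixed at 7.3; the logistic calibration degrades for small nu.
* The Metropolis proposal is isotropic in the 6 free correlations; heavily
  unbalanced posteriors may mix unevenly across pairs.
* Orthant evaluation cost grows linearly in draws × configurations; for
  full 10,000-draw cumulative tables expect hours, as in the original
  analysis.
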