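# mvtlogit

Bayesian multivariate latent Student-*t* regression for **correlated binary
outcomes**, with logistic-calibrated, odds-ratio-interpretable coefficients
and full joint post-hoc risk assessment.

## The problem

Cardiometabolic late effects in survivors of childhood acute lymphoblastic
leukemia — obesity, insulin resistance, (pre-)hypertension, dyslipidemia —
co-occur strongly, yet are usually analyzed one logistic regression at a
time.  `mvtlogit` models the four binary outcomes jointly as sign
indicators of a latent multivariate Student-*t* vector,

&nbsp;&nbsp;&nbsp;&nbsp;Z_i ~ St₄(μ_i, δ²R, ν),&nbsp;&nbsp;Y_i^j = **1**(Z_i^j > 0),&nbsp;&nbsp;μ_i^j = β₀^j + β₁^j T₁ᵢ + β₂^j T₂ᵢ + β_C^j′ C_i,

where T₁/T₂ index a three-level combined corticosteroid-dose /
cranial-radiotherapy exposure (baseline: low dose, no CRT), C_i are
adjustment covariates (sex, age at diagnosis, WBC count at diagnosis, time
since diagnosis), and R is an unstructured residual correlation matrix.
With δ² = π²(ν−2)/(3ν) and ν = 7.3, the latent margin is numerically
indistinguishable from the standard logistic (max CDF gap < 0.002), so each
non-intercept β is a conditional **log odds ratio** — exactly as in a
univariate logistic model — while R captures the outcome dependence that
univariate models discard.

The package provides, as testable units:

* a data-augmented MCMC sampler (gamma scale-mixture; truncated-normal
  latent updates; conjugate coefficient updates; Metropolis step for R with
  a uniform prior over correlation matrices, tuned to ~25% acceptance);
* a batched randomized quasi-Monte-Carlo (Genz-type) integrator for
  multivariate-*t* orthant probabilities — the joint probabilities of the
  2⁴ = 16 outcome configurations;
* post-hoc association measures per posterior draw: conditional ORs,
  g-computation population risk differences (PRDs), configuration
  contrasts, and cumulative contrasts P(N ≥ k) for carrying k or more
  complications, each with equal-tailed 95% credible intervals;
* convergence diagnostics (Geweke z, effective sample size, sequential
  boxplot summaries);
* a calibrated synthetic-cohort generator with known ground truth
  (confounded three-level exposure, heavy-tailed WBC, residually correlated
  outcomes) for end-to-end validation, since the motivating cohort's
  individual-level data are not public;
* a CLI (`mvtlogit simulate | fit | posthoc | report | recovery`) running
  the whole analysis — crude, fully adjusted, and adjusted-without-WBC
  variants — from a single config.

See `docs/methods.md` for the model, algorithms and design choices.

## Worked example

```python
from mvtlogit.simulate import GeneratorSpec, generate_cohort
from mvtlogit.cohort import design_matrix
from mvtlogit.core import ModelSpec
from mvtlogit.sampler import MCMCConfig, fit_latent_t
from mvtlogit import effects

sim = generate_cohort(GeneratorSpec(n=241), seed=1)   # synthetic survivors
X, terms = design_matrix(sim.cohort, "full")
draws = fit_latent_t(sim.cohort.outcomes, X, ModelSpec(),
                     MCMCConfig(n_iter=12_000, n_burn=3_000, thin=4, seed=1),
                     terms=terms)
print(f"retained {draws.n_draws} draws, "
      f"Metropolis acceptance {draws.meta['acceptance_rate']:.2f}")
print(effects.odds_ratios(draws, "t1")["dyslipidemia"])
print(effects.marginal_risk_difference(draws, X, "dyslipidemia", 1))
print(effects.residual_correlation_summary(draws, ("obesity", "insulin_resistance")))
```

prints

```
retained 2250 draws, Metropolis acceptance 0.20
OR dyslipidemia [t1 (+1)]: mean 2.549, median 2.394, 95% CrI (1.249, 4.791)
PRD dyslipidemia [T1 vs T0]: mean 0.184, median 0.184, 95% CrI (0.048, 0.318)
rho obesity~insulin_resistance: mean 0.636, median 0.647, 95% CrI (0.415, 0.791)
```

Reading: in this synthetic cohort (generated with a true dyslipidemia
LD/CRT log-OR of log 1.98 and true obesity–insulin-resistance residual
correlation 0.69), the fitted conditional odds of dyslipidemia under
LD/CRT are ~2.4× the baseline odds (CrI excludes 1); the same contrast
expressed as an absolute excess risk is ~18 dyslipidemia cases per 100
survivors; and the two metabolically linked outcomes remain strongly
correlated after adjustment.  The short desk-scale chain retains 2,250
draws; the package default is the full 1,050,000 / 50,000 / 100 schedule
retaining 10,000.

The full three-variant analysis with report tables:

```bash
mvtlogit report --output-dir report_out --seed 1
```

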