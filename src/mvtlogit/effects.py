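"""Post-hoc association measures computed from posterior draws.

Every measure is evaluated per retained draw and then summarized by its
empirical posterior mean, median and equal-tailed 95% credible interval
(2.5th / 97.5th percentiles, linear interpolation):

* conditional odds ratios  exp(increment * beta) — the logistic-calibrated
  latent-t margin gives non-intercept coefficients a log-odds-ratio reading;
* population risk differences (PRDs) by g-computation: each survivor's
  marginal outcome probability under treatment arm T_l minus under T_0,
  with observed covariates, averaged over all n survivors;
* joint outcome-configuration probability differences via the orthant
  integrals of the latent multivariate t;
* cumulative risk differences P(N >= k), obtained by summing configuration
  contrasts over the patterns with at least k positive outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    DEFAULT_INTEGRATOR,
    IntegratorConfig,
    ModelSpec,
    OutcomeConfiguration,
    all_configurations,
    configuration_probabilities,
    correlation_from_free,
    mvt_rectangle_probability,
)
from .errors import ValidationError
from .sampler import PosteriorDraws


@dataclass(frozen=True)
class AssociationSummary:
    """Posterior summary of one association measure."""

    measure: str                 # OR | PRD | config-PRD | cumulative-PRD | rho
    label: str                   # outcome, configuration pattern, or pair
    contrast: str | None         # e.g. "T1 vs T0"; None for correlations
    mean: float
    median: float
    cri_95: tuple[float, float]

    def __str__(self) -> str:
        lo, hi = self.cri_95
        ctr = f" [{self.contrast}]" if self.contrast else ""
        return (f"{self.measure} {self.label}{ctr}: mean {self.mean:.3f}, "
                f"median {self.median:.3f}, 95% CrI ({lo:.3f}, {hi:.3f})")


def summarize_posterior(values, measure: str = "", label: str = "",
                        contrast: str | None = None) -> AssociationSummary:
    """Empirical mean, median and equal-tailed 95% CrI of per-draw values."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValidationError("need at least 2 draws to summarize")
    lo, hi = np.percentile(v, [2.5, 97.5])  # linear interpolation convention
    return AssociationSummary(measure=measure, label=label, contrast=contrast,
                              mean=float(v.mean()), median=float(np.median(v)),
                              cri_95=(float(lo), float(hi)))


def _contrast_label(level: int) -> str:
    return f"T{level} vs T0"


def _term_index(draws: PosteriorDraws, name: str) -> int:
    terms = draws.meta["terms"]
    if name not in terms:
        raise ValidationError(f"unknown design term {name!r}; have {terms}")
    return terms.index(name)


def odds_ratios(draws: PosteriorDraws, term: str, increment: float = 1.0) -> dict[str, AssociationSummary]:
    """Per-outcome conditional ORs for one design term.

    ``increment`` rescales the coefficient before exponentiation (the WBC
    convention reports exp(10 beta), an OR per 10 x 10^9/L).  Exponentiation
    happens per draw; summaries are computed on the OR scale, with the median
    the headline point estimate (OR posteriors are right-skewed).
    """
    q = draws.meta["q"]
    k = _term_index(draws, term)
    out = {}
    for j, lab in enumerate(draws.meta["outcome_labels"]):
        ors = np.exp(increment * draws.beta_for(j, q)[:, k])
        out[lab] = summarize_posterior(ors, "OR", lab,
                                       contrast=f"{term} (+{increment:g})")
    return out


def _arm_design(X: np.ndarray, draws_meta: dict, level: int) -> np.ndarray:
    """Design matrix with every survivor's treatment dummies set to arm T_level."""
    terms = draws_meta["terms"]
    if level not in (0, 1, 2):
        raise ValidationError(f"unknown treatment level T{level}")
    Xa = np.array(X, dtype=float, copy=True)
    for nm, lev in (("t1", 1), ("t2", 2)):
        if nm in terms:
            Xa[:, terms.index(nm)] = 1.0 if level == lev else 0.0
        elif level == lev:
            raise ValidationError(f"design has no {nm} column for contrast T{level}")
    return Xa


def marginal_risk_difference_draws(draws: PosteriorDraws, X: np.ndarray,
                                   outcome: int | str, level: int,
                                   spec: ModelSpec) -> np.ndarray:
    """Per-draw PRD vector for one outcome and contrast (T_level vs T0)."""
    labels = draws.meta["outcome_labels"]
    j = labels.index(outcome) if isinstance(outcome, str) else int(outcome)
    q = draws.meta["q"]
    Bj = draws.beta_for(j, q)                      # (m, q)
    X1 = _arm_design(X, draws.meta, level)
    X0 = _arm_design(X, draws.meta, 0)
    mu1 = Bj @ X1.T                                # (m, n)
    mu0 = Bj @ X0.T
    p1 = stats.t.cdf(mu1 / spec.delta, df=spec.nu)
    p0 = stats.t.cdf(mu0 / spec.delta, df=spec.nu)
    return (p1 - p0).mean(axis=1)


def marginal_risk_difference(draws: PosteriorDraws, X: np.ndarray,
                             outcome: int | str, level: int,
                             spec: ModelSpec = ModelSpec()) -> AssociationSummary:
    """Population risk difference for one outcome, T_level vs T0."""
    labels = draws.meta["outcome_labels"]
    j = labels.index(outcome) if isinstance(outcome, str) else int(outcome)
    vals = marginal_risk_difference_draws(draws, X, j, level, spec)
    return summarize_posterior(vals, "PRD", labels[j], _contrast_label(level))


def _config_diff_one_draw(beta_mat: np.ndarray, R: np.ndarray, X1, X0,
                          config: OutcomeConfiguration, spec: ModelSpec,
                          integrator: IntegratorConfig, seed: int | None):
    mu1 = X1 @ beta_mat.T
    mu0 = X0 @ beta_mat.T
    p1 = mvt_rectangle_probability(config.lower, config.upper, mu1, R, spec.nu,
                                   integrator=integrator, seed=seed)
    p0 = mvt_rectangle_probability(config.lower, config.upper, mu0, R, spec.nu,
                                   integrator=integrator, seed=seed)
    return float(np.mean(p1 - p0))


def configuration_difference_draws(draws: PosteriorDraws, X: np.ndarray,
                                   config: OutcomeConfiguration, level: int,
                                   spec: ModelSpec,
                                   integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                                   draw_indices: np.ndarray | None = None,
                                   seed: int | None = None) -> np.ndarray:
    """Per-draw averaged configuration probability differences (T_level vs T0)."""
    p, q = draws.meta["p"], draws.meta["q"]
    X1 = _arm_design(X, draws.meta, level)
    X0 = _arm_design(X, draws.meta, 0)
    idx = np.arange(draws.n_draws) if draw_indices is None else np.asarray(draw_indices)
    out = np.empty(idx.size)
    for t, d in enumerate(idx):
        B = draws.beta[d].reshape(p, q)
        R = correlation_from_free(draws.rho[d], p)
        out[t] = _config_diff_one_draw(B, R, X1, X0, config, spec, integrator, seed)
    return out


def configuration_probability_difference(draws: PosteriorDraws, X: np.ndarray,
                                         config: OutcomeConfiguration | tuple,
                                         level: int,
                                         spec: ModelSpec = ModelSpec(),
                                         integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                                         draw_indices: np.ndarray | None = None) -> AssociationSummary:
    """Posterior summary of the averaged joint-configuration contrast."""
    if not isinstance(config, OutcomeConfiguration):
        config = OutcomeConfiguration(tuple(config))
    vals = configuration_difference_draws(draws, X, config, level, spec,
                                          integrator, draw_indices)
    return summarize_posterior(vals, "config-PRD", str(config), _contrast_label(level))


def configuration_table_draws(draws: PosteriorDraws, X: np.ndarray,
                              levels: tuple[int, ...], spec: ModelSpec,
                              integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                              draw_indices: np.ndarray | None = None,
                              seed: int | None = None) -> dict[int, np.ndarray]:
    """Subject-averaged probabilities of all 2^p configurations per draw.

    Returns, for each requested treatment arm, an (n_draws, 2^p) array whose
    entry [d, c] is (1/n) sum_i P(config c | mu_i(arm), R_d).  All
    configurations and subjects share one batched orthant evaluation per
    (draw, arm), which is what makes cumulative contrasts tractable.
    """
    p, q = draws.meta["p"], draws.meta["q"]
    arm_X = {lev: _arm_design(X, draws.meta, lev) for lev in levels}
    idx = np.arange(draws.n_draws) if draw_indices is None else np.asarray(draw_indices)
    out = {lev: np.empty((idx.size, 2**p)) for lev in levels}
    for t, d in enumerate(idx):
        B = draws.beta[d].reshape(p, q)
        R = correlation_from_free(draws.rho[d], p)
        for lev in levels:
            probs = configuration_probabilities(arm_X[lev] @ B.T, R, spec.nu,
                                                integrator=integrator, seed=seed)
            out[lev][t] = probs.mean(axis=0)
    return out


def cumulative_difference_draws(draws: PosteriorDraws, X: np.ndarray, k: int,
                                level: int, spec: ModelSpec,
                                integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                                draw_indices: np.ndarray | None = None,
                                seed: int | None = None) -> np.ndarray:
    """Per-draw cumulative contrast P^{T_l}(N>=k) - P^{T_0}(N>=k), obtained by
    summing the configuration contrasts over patterns with >= k positives."""
    p = draws.meta["p"]
    if not 1 <= k <= p:
        raise ValidationError(f"k must be in [1, {p}]")
    table = configuration_table_draws(draws, X, (0, level), spec, integrator,
                                      draw_indices, seed)
    mask = np.array([c.n_positive >= k for c in all_configurations(p)])
    return (table[level][:, mask] - table[0][:, mask]).sum(axis=1)


def cumulative_risk_difference(draws: PosteriorDraws, X: np.ndarray, k: int,
                               level: int, spec: ModelSpec = ModelSpec(),
                               integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                               draw_indices: np.ndarray | None = None) -> AssociationSummary:
    """Posterior summary of the cumulative PRD for at least k outcomes."""
    vals = cumulative_difference_draws(draws, X, k, level, spec, integrator,
                                       draw_indices)
    return summarize_posterior(vals, "cumulative-PRD", f"N>={k}", _contrast_label(level))


def residual_correlation_summary(draws: PosteriorDraws,
                                 pair: tuple[int, int] | tuple[str, str]) -> AssociationSummary:
    """Posterior summary of one residual latent correlation rho_{jk}."""
    labels = draws.meta["outcome_labels"]
    j, k = pair
    if isinstance(j, str):
        j = labels.index(j)
    if isinstance(k, str):
        k = labels.index(k)
    if j == k:
        raise ValidationError("diagonal correlation is fixed at 1")
    j, k = sorted((j, k))
    p = draws.meta["p"]
    pairs = [(a, b) for a in range(p) for b in range(a + 1, p)]
    col = pairs.index((j, k))
    lab = f"{labels[j]}~{labels[k]}"
    return summarize_posterior(draws.rho[:, col], "rho", lab, None)
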