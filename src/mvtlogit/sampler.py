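"""Data-augmented MCMC for the posterior of (beta, R).

The multivariate t latent vector is represented as a normal scale mixture:
given a per-subject gamma mixing variable phi_i ~ Gamma(nu/2, rate nu/2),

    Z_i | phi_i ~ Normal(mu_i, (delta^2 / phi_i) R),

so that marginally Z_i ~ St_p(mu_i, delta^2 R, nu).  One sweep updates, in
fixed order,

  phi  — conjugate gamma full conditionals,
  Z    — univariate truncated-normal full conditionals per coordinate,
         truncated to (0, inf) when y = 1 and (-inf, 0] when y = 0,
  beta — exact multivariate-normal full conditional of the stacked
         coefficient vector under the independent normal prior
         N(0, diag(1000, 4, ..., 4)) per outcome,
  R    — random-walk Metropolis on the 6 free correlations under the uniform
         prior over valid correlation matrices (proposals outside the space
         count as rejections).

Coefficient stacking is outcome-major: b = (beta^O, beta^I, beta^H, beta^D),
giving posterior precision  P_prior + (1/delta^2) R^{-1} (kron) sum_i phi_i
x_i x_i'.  The proposal scale is tuned by Robbins-Monro toward a 25%
acceptance rate during burn-in only, then frozen, preserving the Markov
property of the retained draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special

from .cohort import CohortData, design_matrix
from .core import (
    ModelSpec,
    correlation_from_free,
    free_from_correlation,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: The published analysis schedule: 1.05M draws, 50k burn-in, thin 100.
FULL_SCHEDULE = dict(n_iter=1_050_000, n_burn=50_000, thin=100)
#: Desk-scale schedule for simulation studies and smoke runs.
REDUCED_SCHEDULE = dict(n_iter=20_000, n_burn=2_000, thin=10)


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = FULL_SCHEDULE["n_iter"]
    n_burn: int = FULL_SCHEDULE["n_burn"]
    thin: int = FULL_SCHEDULE["thin"]
    proposal_scale: float = 0.08
    seed: int = 0
    adapt_during_burnin: bool = True

    def __post_init__(self):
        if not (0 <= self.n_burn < self.n_iter):
            raise ValidationError("require 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class ChainState:
    """Mutable sampler state; Z signs always agree with the observed y."""

    beta: np.ndarray          # stacked (p*q,), outcome-major
    R: np.ndarray             # (p, p) correlation
    Z: np.ndarray             # (n, p) latent matrix
    phi: np.ndarray           # (n,) positive mixing values
    iteration: int = 0
    accept_count: int = 0
    metropolis_count: int = 0
    proposal_scale: float = 0.08

    def beta_matrix(self, p: int, q: int) -> np.ndarray:
        return self.beta.reshape(p, q)


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained thinned draws plus run metadata."""

    beta: np.ndarray              # (m, p*q)
    rho: np.ndarray               # (m, n_pairs)
    beta_columns: tuple[str, ...]
    rho_columns: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def beta_for(self, outcome: int, q: int) -> np.ndarray:
        """(m, q) coefficient draws of one outcome."""
        return self.beta[:, outcome * q:(outcome + 1) * q]

    def column(self, name: str) -> np.ndarray:
        if name in self.beta_columns:
            return self.beta[:, self.beta_columns.index(name)]
        if name in self.rho_columns:
            return self.rho[:, self.rho_columns.index(name)]
        raise KeyError(f"unknown draw column {name!r}")

    def R_matrix(self, draw: int) -> np.ndarray:
        p = self.meta.get("p", 4)
        return correlation_from_free(self.rho[draw], p)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [pd.DataFrame(self.beta, columns=list(self.beta_columns)),
             pd.DataFrame(self.rho, columns=list(self.rho_columns))], axis=1)

    def save(self, prefix) -> None:
        """Persist draws as CSV plus a JSON metadata sidecar."""
        self.to_frame().to_csv(f"{prefix}_draws.csv", index=False)
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=float)

    @classmethod
    def load(cls, prefix) -> "PosteriorDraws":
        df = pd.read_csv(f"{prefix}_draws.csv")
        with open(f"{prefix}_meta.json") as fh:
            meta = json.load(fh)
        beta_cols = [c for c in df.columns if c.startswith("beta_")]
        rho_cols = [c for c in df.columns if c.startswith("rho_")]
        return cls(beta=df[beta_cols].to_numpy(), rho=df[rho_cols].to_numpy(),
                   beta_columns=tuple(beta_cols), rho_columns=tuple(rho_cols),
                   meta=meta)


def draw_column_names(spec: ModelSpec, terms: tuple[str, ...]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    beta_cols = tuple(f"beta_{lab}_{t}" for lab in spec.outcome_labels for t in terms)
    pairs = [(i, j) for i in range(spec.p) for j in range(i + 1, spec.p)]
    rho_cols = tuple(f"rho_{spec.outcome_labels[i]}_{spec.outcome_labels[j]}"
                     for i, j in pairs)
    return beta_cols, rho_cols


def _truncnorm_tail_safe(mean, sd, positive, u):
    """Inverse-CDF draw from a normal truncated at zero, stable in far tails.

    positive=True samples from (0, inf), else from (-inf, 0].  Uses
    log_ndtr / ndtri_exp so the draw stays finite and correctly distributed
    even when the untruncated mass in the allowed half-line is ~1e-300.
    """
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    alpha = -mean / sd  # standardized truncation point
    if positive:
        # X > alpha:  P(X > x) = (1-u) P(X > alpha)
        log_tail = np.log1p(-u) + special.log_ndtr(-alpha)
        x = -special.ndtri_exp(np.minimum(log_tail, -1e-300))
    else:
        # X <= alpha:  P(X <= x) = u P(X <= alpha)
        log_cdf = np.log(np.maximum(u, 1e-300)) + special.log_ndtr(alpha)
        x = special.ndtri_exp(np.minimum(log_cdf, -1e-300))
    return mean + sd * x


def init_state(Y: np.ndarray, X: np.ndarray, spec: ModelSpec,
               config: MCMCConfig) -> ChainState:
    """Starting state: beta = 0, R = I, phi = 1, Z at +/- delta/2 matching y."""
    n, p = Y.shape
    if n == 0:
        raise ValidationError("cannot initialize a chain on an empty cohort")
    q = X.shape[1]
    for j in range(p):
        if Y[:, j].min() == Y[:, j].max():
            logger.warning("outcome %d is constant across the cohort; its intercept "
                           "is only weakly identified", j)
    Z = np.where(Y > 0, spec.delta / 2.0, -spec.delta / 2.0)
    return ChainState(beta=np.zeros(p * q), R=np.eye(p), Z=Z.astype(float),
                      phi=np.ones(n), proposal_scale=config.proposal_scale)


def sample_mixing(state: ChainState, mu: np.ndarray, spec: ModelSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Gamma full-conditional update of the mixing variables.

    phi_i | rest ~ Gamma((nu + p)/2, rate (nu + q_i)/2) with
    q_i = (z_i - mu_i)' (delta^2 R)^{-1} (z_i - mu_i).
    """
    p = spec.p
    E = state.Z - mu
    cf = linalg.cho_factor(state.R, lower=True)
    quad = np.sum(E * linalg.cho_solve(cf, E.T).T, axis=1) / spec.delta_sq
    shape = 0.5 * (spec.nu + p)
    rate = 0.5 * (spec.nu + quad)
    state.phi = rng.gamma(shape, 1.0 / rate)
    return state.phi


def sample_latents(state: ChainState, Y: np.ndarray, mu: np.ndarray,
                   spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal Gibbs update of Z, one coordinate at a time.

    Given phi, Z_i ~ Normal(mu_i, (delta^2/phi_i) R); each coordinate's
    conditional given the others is univariate normal with correlation-driven
    mean shift, truncated to the half-line its observed outcome dictates.
    """
    p = spec.p
    R = state.R
    sd_scale = spec.delta / np.sqrt(state.phi)  # (n,)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        w = np.linalg.solve(R[np.ix_(others, others)], R[others, j])  # (p-1,)
        cond_var_corr = R[j, j] - R[j, others] @ w
        resid = (state.Z[:, others] - mu[:, others])  # (n, p-1)
        cmean = mu[:, j] + resid @ w
        csd = np.sqrt(cond_var_corr) * sd_scale
        u = rng.random(Y.shape[0])
        pos = Y[:, j] > 0
        draws = np.empty(Y.shape[0])
        if pos.any():
            draws[pos] = _truncnorm_tail_safe(cmean[pos], csd[pos], True, u[pos])
        if (~pos).any():
            draws[~pos] = _truncnorm_tail_safe(cmean[~pos], csd[~pos], False, u[~pos])
        state.Z[:, j] = draws
    # enforce the sign invariant exactly (boundary ties go to the closed side)
    state.Z[(Y > 0) & (state.Z <= 0)] = 1e-12
    state.Z[(Y == 0) & (state.Z > 0)] = 0.0
    return state.Z


def beta_full_conditional(state: ChainState, X: np.ndarray, spec: ModelSpec,
                          prior_var: np.ndarray | None = None):
    """Mean and precision of the exact normal full conditional of stacked beta."""
    n, q = X.shape
    p = spec.p
    if prior_var is None:
        pv = np.tile(spec.prior_variances(q), p)
    else:
        pv = np.asarray(prior_var, float)
        if pv.size == q:
            pv = np.tile(pv, p)
    Rinv = np.linalg.inv(state.R)
    S = (X * state.phi[:, None]).T @ X            # sum_i phi_i x_i x_i'
    M = (X * state.phi[:, None]).T @ state.Z      # (q, p)
    prec = np.kron(Rinv, S) / spec.delta_sq + np.diag(1.0 / pv)
    h = (M @ Rinv).T.ravel() / spec.delta_sq      # outcome-major blocks
    cf = linalg.cho_factor(prec, lower=True)
    mean = linalg.cho_solve(cf, h)
    return mean, prec


def sample_beta(state: ChainState, X: np.ndarray, spec: ModelSpec,
                rng: np.random.Generator,
                prior_var: np.ndarray | None = None) -> np.ndarray:
    """Draw the stacked coefficient vector from its normal full conditional."""
    mean, prec = beta_full_conditional(state, X, spec, prior_var)
    L = np.linalg.cholesky(prec)
    z = rng.standard_normal(mean.size)
    state.beta = mean + linalg.solve_triangular(L.T, z, lower=False)
    return state.beta


def _loglik_R(R: np.ndarray, W: np.ndarray, n: int, delta_sq: float) -> float:
    """Normal log-likelihood terms of R given latent residuals.

    W = E' diag(phi) E with E = Z - mu; constant terms cancel in the ratio.
    """
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        return -np.inf
    return -0.5 * n * logdet - 0.5 * np.trace(np.linalg.solve(R, W)) / delta_sq


def update_correlation(state: ChainState, mu: np.ndarray, spec: ModelSpec,
                       rng: np.random.Generator) -> bool:
    """Random-walk Metropolis update of the free correlations.

    The multivariate-normal proposal perturbs the 6 free off-diagonals;
    proposals outside the correlation space are rejected outright, and the
    uniform prior over that space cancels in the acceptance ratio.  A zero
    proposal scale leaves the chain at its current R (counted as accepted by
    convention, recorded in the run metadata).
    """
    p = spec.p
    state.metropolis_count += 1
    rho = free_from_correlation(state.R)
    step = state.proposal_scale * rng.standard_normal(rho.size)
    accepted = False
    if state.proposal_scale == 0.0:
        accepted = True
    else:
        proposal = correlation_from_free(rho + step, p)
        try:
            np.linalg.cholesky(proposal)
            valid = bool(np.all(np.abs(rho + step) < 1.0))
        except np.linalg.LinAlgError:
            valid = False
        if valid:
            E = state.Z - mu
            W = (E * state.phi[:, None]).T @ E
            n = state.Z.shape[0]
            log_ratio = (_loglik_R(proposal, W, n, spec.delta_sq)
                         - _loglik_R(state.R, W, n, spec.delta_sq))
            if np.log(rng.random()) < log_ratio:
                state.R = proposal
                accepted = True
    if accepted:
        state.accept_count += 1
    return accepted


def burn_and_thin(raw: np.ndarray, config: MCMCConfig) -> np.ndarray:
    """Drop the first n_burn draws, keep every thin-th thereafter starting at
    the first post-burn-in draw."""
    raw = np.asarray(raw)
    if raw.shape[0] != config.n_iter:
        raise ValidationError("raw draw count must equal n_iter")
    kept = raw[config.n_burn::config.thin]
    if kept.shape[0] == 0:
        raise ValidationError("schedule retains no draws")
    if (config.n_iter - config.n_burn) % config.thin:
        logger.info("burn_and_thin: schedule not divisible; retaining %d draws",
                    kept.shape[0])
    return kept


def fit_latent_t(Y: np.ndarray, X: np.ndarray, spec: ModelSpec, config: MCMCConfig,
                 terms: tuple[str, ...] | None = None,
                 prior_var: np.ndarray | None = None) -> PosteriorDraws:
    """Run the full data-augmented chain on raw outcome/design matrices.

    Applies burn-in and thinning on the fly (only retained draws are stored)
    and records the post-burn-in Metropolis acceptance rate.  Fully
    reproducible from ``config.seed``.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n, p = Y.shape
    q = X.shape[1]
    if spec.p != p:
        spec = ModelSpec(p=p, nu=spec.nu, outcome_labels=tuple(str(j) for j in range(p)),
                         prior_var_intercept=spec.prior_var_intercept,
                         prior_var_slope=spec.prior_var_slope)
    if terms is None:
        terms = tuple(f"x{k}" for k in range(q))
    rng = np.random.default_rng(config.seed)
    state = init_state(Y, X, spec, config)
    beta_cols, rho_cols = draw_column_names(spec, terms)
    m = config.n_retained
    beta_out = np.empty((m, p * q))
    rho_out = np.empty((m, p * (p - 1) // 2))
    kept = 0
    post_burn_accept = 0
    post_burn_total = 0
    for it in range(config.n_iter):
        mu = X @ state.beta_matrix(p, q).T  # (n, p)
        sample_mixing(state, mu, spec, rng)
        sample_latents(state, Y, mu, spec, rng)
        sample_beta(state, X, spec, rng, prior_var)
        mu = X @ state.beta_matrix(p, q).T
        accepted = update_correlation(state, mu, spec, rng)
        state.iteration = it + 1
        in_burn = it < config.n_burn
        if in_burn and config.adapt_during_burnin and state.proposal_scale > 0:
            # Robbins-Monro step toward 25% acceptance, frozen after burn-in
            gamma = (it + 1) ** -0.6
            state.proposal_scale *= np.exp(gamma * ((1.0 if accepted else 0.0) - 0.25))
        if not in_burn:
            post_burn_total += 1
            post_burn_accept += int(accepted)
            offset = it - config.n_burn
            if offset % config.thin == 0 and kept < m:
                beta_out[kept] = state.beta
                rho_out[kept] = free_from_correlation(state.R)
                kept += 1
    meta = dict(n_iter=config.n_iter, n_burn=config.n_burn, thin=config.thin,
                seed=config.seed, n=n, p=p, q=q, nu=spec.nu,
                terms=list(terms), outcome_labels=list(spec.outcome_labels),
                proposal_scale_final=float(state.proposal_scale),
                acceptance_rate=(post_burn_accept / post_burn_total
                                 if post_burn_total else float("nan")))
    return PosteriorDraws(beta=beta_out[:kept], rho=rho_out[:kept],
                          beta_columns=beta_cols, rho_columns=rho_cols, meta=meta)


def run_chain(cohort: CohortData, spec: ModelSpec, config: MCMCConfig,
              covariate_set: str = "full", wbc_form: str = "identity") -> PosteriorDraws:
    """Fit the model to a cohort: builds the design, runs the sampler."""
    X, terms = design_matrix(cohort, covariate_set, wbc_form)
    draws = fit_latent_t(cohort.outcomes, X, spec, config, terms=terms)
    draws.meta.update(covariate_set=covariate_set, wbc_form=wbc_form)
    return draws
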