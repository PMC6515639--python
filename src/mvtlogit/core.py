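"""Distributional kernel of the latent multivariate Student-t model.

The model links a vector of p correlated binary outcomes Y = (Y^1, ..., Y^p)
to a latent multivariate Student-t vector Z with location mu, scale matrix
delta^2 * R and nu degrees of freedom through Y^j = 1(Z^j > 0).  With
delta^2 = pi^2 (nu - 2) / (3 nu) and nu = 7.3 the marginal latent law is
numerically very close to the standard logistic distribution, so every
non-intercept regression coefficient in mu keeps the familiar conditional
log-odds-ratio interpretation of a univariate logistic model while R captures
residual dependence between outcomes.

This module provides the density, the logistic calibration constant, joint
outcome-configuration (orthant) probabilities via a deterministic-seeded
randomized quasi-Monte-Carlo routine of the Genz separation-of-variables
type, the observation likelihood, and marginal outcome probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats
from scipy.stats import qmc

from .errors import IntegrationError, ValidationError

DEFAULT_NU = 7.3
#: Default seed of the scrambled Sobol' sequence; fixed so that repeated calls
#: in the same context return identical values.
INTEGRATOR_SEED = 101

OUTCOME_LABELS = ("obesity", "insulin_resistance", "pre_hypertension", "dyslipidemia")

#: Order of the 6 free correlation elements for p = 4 (upper triangle, row major).
CORRELATION_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def scale_constant(nu: float) -> float:
    """Scale constant delta^2 = pi^2 (nu - 2) / (3 nu) of the latent t law.

    Calibrates the t(nu) margin to the standard logistic distribution; it is
    positive only for nu > 2 (finite latent variance).
    """
    if not nu > 2:
        raise ValueError(f"nu must exceed 2 for a finite scale constant, got {nu}")
    return np.pi**2 * (nu - 2.0) / (3.0 * nu)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed distributional constants and prior layout of one model fit.

    delta_sq is always recomputed from nu (never stored) so the two cannot
    drift apart.
    """

    p: int = 4
    nu: float = DEFAULT_NU
    outcome_labels: tuple[str, ...] = OUTCOME_LABELS
    prior_var_intercept: float = 1000.0
    prior_var_slope: float = 4.0
    design_width: int | None = None

    def __post_init__(self):
        if not self.nu > 2:
            raise ValueError("nu must exceed 2")
        if len(self.outcome_labels) != self.p:
            raise ValueError("outcome_labels must have length p")

    @property
    def delta_sq(self) -> float:
        return scale_constant(self.nu)

    @property
    def delta(self) -> float:
        return float(np.sqrt(self.delta_sq))

    def prior_variances(self, design_width: int) -> np.ndarray:
        """Per-term prior variances for one outcome: (1000, 4, ..., 4)."""
        v = np.full(design_width, self.prior_var_slope)
        v[0] = self.prior_var_intercept
        return v


@dataclass(frozen=True)
class CoefficientSet:
    """Per-outcome regression coefficient vectors on the log-odds scale.

    ``matrix`` has one row per outcome (shape p x design_width); ``stacked``
    concatenates rows outcome-major, matching the sampler's convention.
    """

    matrix: np.ndarray
    terms: tuple[str, ...]
    outcome_labels: tuple[str, ...] = OUTCOME_LABELS

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape != (len(self.outcome_labels), len(self.terms)):
            raise ValidationError("coefficient matrix shape must be (p, design_width)")
        if not np.all(np.isfinite(m)):
            raise ValidationError("coefficients must be finite")

    @property
    def stacked(self) -> np.ndarray:
        return self.matrix.ravel()


@dataclass(frozen=True)
class OutcomeConfiguration:
    """One of the 2^p joint outcome patterns with its orthant limits.

    pattern_j = 1 maps to the latent half-line (0, inf) and pattern_j = 0 to
    (-inf, 0]; semi-infinite limits are represented by +/-inf sentinels.
    """

    pattern: tuple[int, ...]

    def __post_init__(self):
        if any(v not in (0, 1) for v in self.pattern):
            raise ValidationError("configuration pattern entries must be 0/1")

    @property
    def p(self) -> int:
        return len(self.pattern)

    @property
    def n_positive(self) -> int:
        return int(sum(self.pattern))

    @property
    def lower(self) -> np.ndarray:
        return np.where(np.asarray(self.pattern) == 1, 0.0, -np.inf)

    @property
    def upper(self) -> np.ndarray:
        return np.where(np.asarray(self.pattern) == 1, np.inf, 0.0)

    def __str__(self) -> str:  # e.g. "1001"
        return "".join(str(v) for v in self.pattern)


@lru_cache(maxsize=None)
def all_configurations(p: int = 4) -> tuple[OutcomeConfiguration, ...]:
    """All 2^p outcome configurations, lexicographic with the first outcome
    as the most significant bit (deterministic report ordering)."""
    configs = []
    for k in range(2**p):
        pattern = tuple((k >> (p - 1 - j)) & 1 for j in range(p))
        configs.append(OutcomeConfiguration(pattern))
    return tuple(configs)


def correlation_from_free(rho: np.ndarray, p: int = 4) -> np.ndarray:
    """Assemble a symmetric unit-diagonal matrix from its free off-diagonals
    (upper triangle, row-major order)."""
    rho = np.asarray(rho, dtype=float)
    R = np.eye(p)
    iu = np.triu_indices(p, k=1)
    R[iu] = rho
    R[(iu[1], iu[0])] = rho
    return R


def free_from_correlation(R: np.ndarray) -> np.ndarray:
    """Extract the free off-diagonal elements (upper triangle, row-major)."""
    R = np.asarray(R, dtype=float)
    return R[np.triu_indices(R.shape[0], k=1)]


def is_valid_correlation(R: np.ndarray, tol: float = 1e-10) -> bool:
    """Unit diagonal, symmetric, strictly positive definite."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        return False
    if not np.allclose(np.diag(R), 1.0, atol=tol):
        return False
    if not np.allclose(R, R.T, atol=tol):
        return False
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return False
    return True


def validate_correlation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if not is_valid_correlation(R):
        raise ValidationError("R must be a symmetric positive-definite correlation matrix")
    return R


def mvt_logdensity(t, mu, scale, nu: float) -> float | np.ndarray:
    """Log density of the multivariate Student-t St_p(t | mu, scale, nu).

    ``scale`` must be symmetric positive definite; evaluation is vectorized
    over leading axes of ``t``.
    """
    scale = np.asarray(scale, dtype=float)
    if scale.ndim == 0:
        scale = scale.reshape(1, 1)
    return stats.multivariate_t.logpdf(t, loc=np.asarray(mu, float), shape=scale, df=nu)


@dataclass(frozen=True)
class IntegratorConfig:
    """Accuracy settings of the randomized-QMC orthant integrator.

    ``n_points`` scrambled Sobol' points per randomization, ``n_reps``
    independent randomizations (their spread gives the error estimate),
    doubling the point count up to ``max_refinements`` times when the
    3-sigma error estimate exceeds ``target_abs_error``.
    """

    n_points: int = 2048
    n_reps: int = 8
    target_abs_error: float = 5e-4
    max_refinements: int = 2
    check_error: bool = True

    def relaxed(self) -> "IntegratorConfig":
        """A cheaper preset for inner loops over many posterior draws, where
        per-draw integration noise (~1e-3) is far below posterior spread."""
        return IntegratorConfig(n_points=256, n_reps=3, target_abs_error=5e-3,
                                max_refinements=0, check_error=False)


DEFAULT_INTEGRATOR = IntegratorConfig()


def _genz_t_rectangle(a: np.ndarray, b: np.ndarray, L: np.ndarray, nu: float,
                      u: np.ndarray) -> np.ndarray:
    """One QMC estimate of P(a < T <= b) for T ~ St_p(0, L L', nu).

    Separation-of-variables: the first QMC coordinate drives the chi mixing
    variable s = sqrt(chi2_nu / nu) (conditional on s the vector is normal
    with the region limits scaled by s), the remaining p-1 coordinates drive
    the sequential conditional-normal construction.  Batched over rows of the
    limit arrays ``a``, ``b`` (shape (B, p)).
    """
    B, p = a.shape
    s = np.sqrt(stats.chi2.ppf(u[:, 0], nu) / nu)  # (N,)
    prob = np.ones((B, u.shape[0]))
    ys: list[np.ndarray] = []
    for k in range(p):
        center = 0.0
        for j in range(k):
            center = center + L[k, j] * ys[j]
        lo = (a[:, k, None] * s[None, :] - center) / L[k, k]
        hi = (b[:, k, None] * s[None, :] - center) / L[k, k]
        d = special.ndtr(lo)
        e = special.ndtr(hi)
        f = np.clip(e - d, 0.0, 1.0)
        prob *= f
        if k < p - 1:
            q = np.clip(d + u[None, :, k + 1] * f, 1e-15, 1 - 1e-15)
            ys.append(special.ndtri(q))
    return prob.mean(axis=1)


def mvt_rectangle_probability(lower, upper, mu, R, nu: float = DEFAULT_NU, *,
                              delta_sq: float | None = None,
                              integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                              seed: int | None = None,
                              return_error: bool = False):
    """P(lower < T <= upper) for T ~ St_p(mu, delta^2 R, nu), batched over mu.

    ``mu`` may be a single p-vector or an (B, p) array sharing the same R
    (the batch form is what the g-computation post-hoc layer uses); the
    limits may likewise be (p,) vectors shared across the batch or (B, p)
    arrays paired row-by-row with ``mu``.  Semi-infinite limits are passed
    as +/-inf.  Returns probabilities in [0, 1]; with ``return_error`` also
    the 3-sigma randomization error estimate.  Raises
    :class:`IntegrationError` if the target accuracy is not reached within
    the refinement cap (when ``integrator.check_error``).
    """
    R = validate_correlation(R)
    if delta_sq is None:
        delta_sq = scale_constant(nu)
    delta = np.sqrt(delta_sq)
    mu_arr = np.atleast_2d(np.asarray(mu, dtype=float))
    scalar = np.asarray(mu).ndim == 1
    p = R.shape[0]
    if mu_arr.shape[1] != p:
        raise ValidationError("mu dimension must match R")
    lower = np.broadcast_to(np.asarray(lower, dtype=float), mu_arr.shape)
    upper = np.broadcast_to(np.asarray(upper, dtype=float), mu_arr.shape)
    # Standardize: T = mu + delta * (L u) / s with u normal, s chi-based.
    with np.errstate(invalid="ignore"):
        a = (lower - mu_arr) / delta
        b = (upper - mu_arr) / delta
    L = np.linalg.cholesky(R)
    rng = np.random.default_rng(INTEGRATOR_SEED if seed is None else seed)
    n_points = integrator.n_points
    for _ in range(integrator.max_refinements + 1):
        reps = np.empty((integrator.n_reps, mu_arr.shape[0]))
        for r in range(integrator.n_reps):
            eng = qmc.Sobol(d=p, scramble=True, seed=rng)
            u = eng.random(n_points)
            reps[r] = _genz_t_rectangle(a, b, L, nu, u)
        value = reps.mean(axis=0)
        err = 3.0 * reps.std(axis=0, ddof=1) / np.sqrt(integrator.n_reps)
        if err.max() <= integrator.target_abs_error:
            break
        n_points *= 2
    else:
        if integrator.check_error:
            raise IntegrationError(
                f"orthant probability accuracy {err.max():.2e} exceeds target "
                f"{integrator.target_abs_error:.2e} after refinement cap",
                achieved_error=float(err.max()),
            )
    value = np.clip(value, 0.0, 1.0)
    if scalar:
        value, err = float(value[0]), float(err[0])
    if return_error:
        return value, err
    return value


def orthant_probability(mu, R, nu: float = DEFAULT_NU,
                        config: OutcomeConfiguration | tuple[int, ...] = (1, 1, 1, 1), *,
                        integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                        seed: int | None = None, return_error: bool = False):
    """P(Z in the configuration's orthant) for Z ~ St_p(mu, delta^2 R, nu).

    This is the joint probability of the binary outcome pattern encoded by
    ``config``; batched over rows when ``mu`` is a matrix.
    """
    if not isinstance(config, OutcomeConfiguration):
        config = OutcomeConfiguration(tuple(config))
    return mvt_rectangle_probability(config.lower, config.upper, mu, R, nu,
                                     integrator=integrator, seed=seed,
                                     return_error=return_error)


def configuration_probabilities(mu, R, nu: float = DEFAULT_NU,
                                configs: tuple[OutcomeConfiguration, ...] | None = None, *,
                                integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                                seed: int | None = None) -> np.ndarray:
    """Joint probabilities of every outcome configuration at each location.

    Stacks all configurations and all rows of ``mu`` into one batched QMC
    evaluation (one Cholesky, one Sobol' stream), returning an array of shape
    (n_locations, n_configs) — the workhorse of the cumulative risk
    contrasts, where per-config calls would be prohibitively slow.
    """
    mu_arr = np.atleast_2d(np.asarray(mu, dtype=float))
    p = mu_arr.shape[1]
    if configs is None:
        configs = all_configurations(p)
    n_loc, n_cfg = mu_arr.shape[0], len(configs)
    lower = np.vstack([np.tile(c.lower, (n_loc, 1)) for c in configs])
    upper = np.vstack([np.tile(c.upper, (n_loc, 1)) for c in configs])
    mu_tiled = np.tile(mu_arr, (n_cfg, 1))
    flat = mvt_rectangle_probability(lower, upper, mu_tiled, R, nu,
                                     integrator=integrator, seed=seed)
    return np.asarray(flat).reshape(n_cfg, n_loc).T


def observation_likelihood(y, design_row, beta: CoefficientSet | np.ndarray,
                           R, spec: ModelSpec = ModelSpec(), *,
                           integrator: IntegratorConfig = DEFAULT_INTEGRATOR,
                           seed: int | None = None) -> float:
    """Likelihood P(Y = y | x, beta, R): the orthant integral of the latent t
    density at mu = B x over the region that the observed pattern selects."""
    y = tuple(int(v) for v in np.asarray(y).ravel())
    if any(v not in (0, 1) for v in y):
        raise ValidationError("y must be a binary pattern")
    B = beta.matrix if isinstance(beta, CoefficientSet) else np.asarray(beta, float)
    x = np.asarray(design_row, dtype=float)
    mu = B @ x
    return orthant_probability(mu, R, spec.nu, OutcomeConfiguration(y),
                               integrator=integrator, seed=seed)


def marginal_outcome_probability(mu_j, spec: ModelSpec = ModelSpec()):
    """P(Z^j > 0) = F_nu(mu_j / delta): marginal success probability of one
    outcome given its linear predictor (unit correlation entry makes the
    margin a scaled univariate t)."""
    return stats.t.cdf(np.asarray(mu_j, dtype=float) / spec.delta, df=spec.nu)


def logistic_approx_gap(spec: ModelSpec = ModelSpec(),
                        grid: np.ndarray | None = None) -> float:
    """Max absolute gap between the standard logistic CDF and the delta-scaled
    t(nu) CDF over a dense grid — the calibration self-test that justifies the
    log-odds-ratio reading of the coefficients."""
    if grid is None:
        grid = np.arange(-10.0, 10.0 + 1e-9, 0.01)
    gap = np.abs(special.expit(grid) - stats.t.cdf(grid / spec.delta, df=spec.nu))
    return float(gap.max())
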