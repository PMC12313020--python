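"""Temporary (partial) state expectancies between two ages.

The expected years spent in living state s between ``age_start`` and
``age_end`` is the integral of the occupancy probability

    e_s = int_{a}^{b} p_s(u) du,
    p_s(u) = sum_r pi_r(a) P_{r s}(a, u)   (marginal start), or
    p_s(u) = P_{r s}(a, u)                 (conditional on start state r)

with pi the state distribution at the starting age (a fitted prevalence
model or an explicit distribution).  Working life expectancy is the sum
of the two working-state expectancies; total life expectancy the sum
over the three living states.

Three integration rules are provided:

* ``step`` (default): exact integration of the step-intensity occupancy
  curve — within each grid cell the intensities are frozen at the left
  endpoint, and the integral of the resulting matrix-exponential segment
  has a closed (augmented-matrix) form.  Exact for models whose
  intensities really are piecewise constant on the grid.
* ``middle_riemann``: midpoint Riemann sum of the occupancy curve.
* ``simpson``: composite Simpson's rule (requires an even number of
  sub-intervals; the step is auto-adjusted otherwise, with a log note).

95% confidence intervals follow the parametric-simulation recipe:
parameter vectors are drawn from a multivariate normal centered at the
estimates with the fitted covariance, every expectancy is recomputed per
draw, and the 2.5th/97.5th percentiles are reported (500 draws by
default).  Point estimates remain the plug-in values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._expm import expm_batch, expm_with_integral
from .transitions import GompertzParams, alive_generator
from .prevalence import StatePrevalenceResults

logger = logging.getLogger(__name__)

STATE_KEYS = ("healthy_working", "unhealthy_working", "not_working")
ALL_KEYS = STATE_KEYS + ("wle", "total")

INTEGRATION_METHODS = ("step", "middle_riemann", "simpson")


@dataclass(frozen=True)
class IntegrationSpec:
    """Quadrature rule, step and age window of the expectancy integral."""

    method: str = "step"
    step_h: float = 0.1
    age_start: float = 51.0
    age_end: float = 80.0

    def __post_init__(self) -> None:
        if self.method not in INTEGRATION_METHODS:
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.step_h <= 0:
            raise ValueError("step_h must be positive")
        if self.age_end <= self.age_start:
            raise ValueError("age_end must exceed age_start")


@dataclass
class ExpectancySet:
    """State-specific or marginal temporary expectancies, with optional CIs."""

    estimates: dict
    ci_lower: dict | None = None
    ci_upper: dict | None = None
    spec: IntegrationSpec | None = None
    start_mode: str = "marginal"
    covariates: tuple = ()
    n_draws: int | None = None
    seed: int | None = None

    def __getitem__(self, key):
        return self.estimates[key]

    @property
    def wle(self) -> float:
        return self.estimates["wle"]

    @property
    def total(self) -> float:
        return self.estimates["total"]


def _start_distribution(prevalence, age_start, covariates, start_mode):
    if isinstance(start_mode, str) and start_mode.startswith("state"):
        r = int(start_mode.split(":")[1]) if ":" in start_mode else int(start_mode[-1])
        pi = np.zeros(3)
        pi[r - 1] = 1.0
        return pi
    if start_mode != "marginal":
        raise ValueError(f"unknown start_mode {start_mode!r}")
    if isinstance(prevalence, StatePrevalenceResults):
        return prevalence.state_probabilities(age_start, covariates)
    pi = np.asarray(prevalence, float).reshape(3)
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("start distribution must sum to 1")
    return pi


def _resolve_spec(spec: IntegrationSpec) -> tuple[IntegrationSpec, int]:
    width = spec.age_end - spec.age_start
    n = int(round(width / spec.step_h))
    if abs(n * spec.step_h - width) > 1e-9 * max(1.0, width):
        n = int(np.ceil(width / spec.step_h))
    if spec.method == "simpson" and n % 2 == 1:
        n += 1
        logger.info("simpson needs an even number of sub-intervals; "
                    "step adjusted to %.6g", width / n)
    return replace(spec, step_h=width / n), n


def occupancy_curve(params: GompertzParams, spec: IntegrationSpec,
                    covariates=(), refine: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Living-block occupancy matrices P(age_start, u) on the grid.

    Returns (ages, P) with P of shape (len(ages), 3, 3); row r is the
    occupancy distribution over living states starting from state r+1.
    ``refine`` subdivides each step for curves sampled at midpoints.
    """
    spec, n = _resolve_spec(spec)
    h = spec.step_h / refine
    ages = spec.age_start + h * np.arange(n * refine + 1)
    A = alive_generator(params, ages[:-1], covariates)
    E = expm_batch(A * h)
    P = np.empty((len(ages), 3, 3))
    P[0] = np.eye(3)
    for k in range(len(ages) - 1):
        P[k + 1] = P[k] @ E[k]
    return ages, P


def occupancy_probability(params: GompertzParams, u: float,
                          prevalence=None, covariates=(),
                          start_mode="marginal", age_start: float = 51.0,
                          step_h: float = 0.1, target_state=None):
    """Probability of occupying each state (or ``target_state``) at age u.

    Marginal mode weights the start states by the state distribution at
    ``age_start``; ``state:r`` mode conditions on starting in state r.
    The dead-state entry is included (last component) so the four sum
    to 1.
    """
    if u < age_start:
        raise ValueError("u must not precede age_start")
    pi = _start_distribution(prevalence, age_start, covariates, start_mode)
    if u == age_start:
        occ3 = pi
    else:
        spec, _ = _resolve_spec(IntegrationSpec("step", step_h, age_start, u))
        _, P = occupancy_curve(params, spec, covariates)
        occ3 = pi @ P[-1]
    occ = np.concatenate([occ3, [1.0 - occ3.sum()]])
    if target_state is not None:
        return occ[target_state - 1]
    return occ


def temporary_expectancy(params_or_results, prevalence=None,
                         spec: IntegrationSpec | None = None,
                         covariates=(), start_mode="marginal") -> ExpectancySet:
    """Point estimates of the temporary expectancies on the age window.

    ``params_or_results`` may be a GompertzParams or a fitted
    GompertzMultistateResults; ``prevalence`` a fitted
    StatePrevalenceResults or an explicit length-3 start distribution
    (ignored in ``state:r`` mode).
    """
    params = _as_params(params_or_results)
    spec = spec or IntegrationSpec()
    pi = _start_distribution(prevalence, spec.age_start, covariates, start_mode)
    e3 = _integrate_living(params, spec, covariates, pi)
    est = {k: float(v) for k, v in zip(STATE_KEYS, e3)}
    est["wle"] = est["healthy_working"] + est["unhealthy_working"]
    est["total"] = float(e3.sum())
    return ExpectancySet(estimates=est, spec=spec, start_mode=str(start_mode),
                         covariates=tuple(np.atleast_1d(covariates))
                         if np.size(covariates) else ())


def _as_params(obj) -> GompertzParams:
    if isinstance(obj, GompertzParams):
        return obj
    return obj.gompertz_params()


def _integrate_living(params, spec, covariates, pi) -> np.ndarray:
    """Vector of expected years in the three living states."""
    rspec, n = _resolve_spec(spec)
    h = rspec.step_h
    if rspec.method == "step":
        ages = rspec.age_start + h * np.arange(n + 1)
        A = alive_generator(params, ages[:-1], covariates)
        E, F = expm_with_integral(A, h)
        p = pi.copy()
        e = np.zeros(3)
        for k in range(n):
            e += p @ F[k]
            p = p @ E[k]
        return e
    if rspec.method == "middle_riemann":
        _, P = occupancy_curve(params, rspec, covariates, refine=2)
        mid = P[1::2]  # midpoints of each step
        occ = np.einsum("r,krs->ks", pi, mid)
        return h * occ.sum(axis=0)
    # simpson
    _, P = occupancy_curve(params, rspec, covariates)
    occ = np.einsum("r,krs->ks", pi, P)
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return (h / 3.0) * (w[:, None] * occ).sum(axis=0)


def nearest_psd(cov: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues to zero; report whether repair was needed."""
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    if w.min() >= -1e-12 * max(1.0, w.max()):
        return cov, False
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T, True


def mvn_percentile_ci(theta: np.ndarray, cov: np.ndarray, statistic,
                      n_draws: int = 500, seed: int | None = None,
                      level: float = 0.95):
    """Percentile CI of ``statistic(theta_draw)`` under MVN parameter draws.

    The reusable core of the simulation-based intervals: draws are
    ``theta + L z`` with ``L`` the (PSD-repaired) Cholesky-like factor of
    ``cov``; the statistic may return a scalar or a 1-d array.
    """
    theta = np.asarray(theta, float)
    cov, repaired = nearest_psd(np.asarray(cov, float))
    if repaired:
        logger.warning("covariance not positive semi-definite; "
                       "negative eigenvalues clipped to zero")
    w, V = np.linalg.eigh(cov)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    draws = theta + rng.standard_normal((n_draws, theta.size)) @ L.T
    vals = np.asarray([np.atleast_1d(statistic(d)) for d in draws], float)
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(vals, 100 * alpha, axis=0)
    hi = np.percentile(vals, 100 * (1 - alpha), axis=0)
    return lo, hi, vals


def simulate_confidence_intervals(results, prevalence=None,
                                  spec: IntegrationSpec | None = None,
                                  covariates=(), start_mode="marginal",
                                  n_draws: int = 500, seed: int | None = None,
                                  level: float = 0.95) -> ExpectancySet:
    """Expectancies with simulation-based percentile confidence intervals.

    Draws the multistate parameters (and, in marginal mode, the
    prevalence parameters, independently) from multivariate normals
    centered at the estimates, recomputes every expectancy per draw, and
    takes percentiles; derived sums (WLE, total) are percentiled from
    the per-draw sums so each draw stays internally coherent.
    """
    if results.cov_params is None or not results.cov_usable:
        raise ValueError("fit has no usable covariance; CIs unavailable")
    spec = spec or IntegrationSpec()
    point = temporary_expectancy(results, prevalence, spec, covariates,
                                 start_mode)

    theta_m = results.params
    cov_m = results.cov_params
    draw_prev = (start_mode == "marginal"
                 and isinstance(prevalence, StatePrevalenceResults)
                 and prevalence.cov_flat is not None)
    if draw_prev:
        theta = np.concatenate([theta_m, prevalence.flat_params])
        cov = np.zeros((theta.size, theta.size))
        cov[:theta_m.size, :theta_m.size] = cov_m
        cov[theta_m.size:, theta_m.size:] = prevalence.cov_flat
    else:
        theta, cov = theta_m, cov_m

    def stat(th):
        params = results.structure.unpack(th[:theta_m.size])
        prev = (prevalence.with_params(th[theta_m.size:]) if draw_prev
                else prevalence)
        es = temporary_expectancy(params, prev, spec, covariates, start_mode)
        return np.array([es.estimates[k] for k in ALL_KEYS])

    lo, hi, _ = mvn_percentile_ci(theta, cov, stat, n_draws, seed, level)
    return ExpectancySet(
        estimates=point.estimates,
        ci_lower=dict(zip(ALL_KEYS, map(float, lo))),
        ci_upper=dict(zip(ALL_KEYS, map(float, hi))),
        spec=spec, start_mode=str(start_mode), covariates=point.covariates,
        n_draws=n_draws, seed=seed)
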