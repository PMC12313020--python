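"""Maximum-likelihood fitting of the Gompertz multistate model.

The central objects follow the statsmodels convention:

* :class:`GompertzMultistateModel` is built from a model-ready panel
  (see :mod:`hwle.states`) plus a specification (covariate set, grid
  step, tied or transition-specific age slopes);
* ``model.fit()`` returns a :class:`GompertzMultistateResults` carrying
  the estimates, the covariance matrix from the inverse observed
  information, diagnostics, Wald intervals and a ``summary()`` table.

Estimation is unconstrained quasi-Newton (L-BFGS-B without bounds) on
the working scale: log baseline intensities, linear age slopes, linear
covariate log-ratios.  Gradients are central finite differences (step
1e-5); the observed information is a central finite-difference Hessian
of the negative log-likelihood at the optimum, symmetrized.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import PanelIntervals, compile_intervals, total_log_likelihood
from .transitions import DEAD, GompertzParams, TRANSITIONS

logger = logging.getLogger(__name__)

#: covariate set name -> panel columns used
COVARIATE_SETS = {
    "none": (),
    "gender": ("gender01",),
    "education": ("education01",),
    "gender+education": ("gender01", "education01"),
}

_CRUDE_RATE_FLOOR = 1e-3


@dataclass
class ModelSpecification:
    """Which covariates enter, whether age slopes are tied, and the grid."""

    covariate_set: str = "none"
    tie_age_slopes: bool = False
    grid_step: float = 0.5

    def __post_init__(self) -> None:
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate_set {self.covariate_set!r}; "
                             f"choose from {sorted(COVARIATE_SETS)}")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")

    @property
    def covariate_columns(self) -> tuple[str, ...]:
        return COVARIATE_SETS[self.covariate_set]


class ParameterStructure:
    """Mapping between the flat working vector and GompertzParams blocks.

    Vector layout: betas for active transitions, then age slopes (one
    per active transition, or a single shared slope when tied), then
    covariate coefficients transition-major.
    """

    def __init__(self, covariate_columns=(), tie_age_slopes: bool = False,
                 active=None, x0: float = 51.0):
        self.covariate_columns = tuple(covariate_columns)
        self.tie_age_slopes = bool(tie_age_slopes)
        self.active = (np.ones(9, bool) if active is None
                       else np.asarray(active, bool))
        self.x0 = float(x0)
        self._act_idx = np.nonzero(self.active)[0]
        self.n_active = len(self._act_idx)
        self.k = len(self.covariate_columns)
        self.n_xi = 1 if self.tie_age_slopes else self.n_active
        self.n_params = self.n_active + self.n_xi + self.n_active * self.k

    def names(self) -> list[str]:
        lab = [f"q{r}{s}" for r, s in TRANSITIONS]
        out = [f"{lab[t]}.beta" for t in self._act_idx]
        if self.tie_age_slopes:
            out.append("xi")
        else:
            out += [f"{lab[t]}.xi" for t in self._act_idx]
        for t in self._act_idx:
            out += [f"{lab[t]}.{c}" for c in self.covariate_columns]
        return out

    def unpack(self, theta: np.ndarray) -> GompertzParams:
        theta = np.asarray(theta, float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, "
                             f"got {theta.shape}")
        beta = np.full(9, -np.inf)
        xi = np.zeros(9)
        gamma = np.zeros((9, self.k))
        na = self.n_active
        beta[self._act_idx] = theta[:na]
        if self.tie_age_slopes:
            xi[self._act_idx] = theta[na]
        else:
            xi[self._act_idx] = theta[na:na + self.n_xi]
        g = theta[na + self.n_xi:].reshape(na, self.k) if self.k else \
            np.zeros((na, 0))
        gamma[self._act_idx] = g
        beta[~self.active] = 0.0  # inert; masked by `active`
        return GompertzParams(beta=beta, xi=xi, gamma=gamma,
                              active=self.active, x0=self.x0)

    def pack(self, params: GompertzParams) -> np.ndarray:
        parts = [params.beta[self._act_idx]]
        if self.tie_age_slopes:
            parts.append(params.xi[self._act_idx][:1])
        else:
            parts.append(params.xi[self._act_idx])
        if self.k:
            parts.append(params.gamma[self._act_idx].ravel())
        return np.concatenate(parts)


def initialize_parameters(panel: pd.DataFrame, structure: ParameterStructure
                          ) -> np.ndarray:
    """Starting values: log crude occurrence/exposure rates, zero slopes.

    Crude rate of transition (r, s) = observed r->s moves between
    consecutive records / person-years spent at risk in state r, floored
    at 1e-3 per year (with a warning when a permitted transition is
    never observed).
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    counts = np.zeros((4, 4))
    exposure = np.zeros(4)
    # sorted iteration keeps the accumulation order (hence the start value,
    # hence the optimizer trajectory) invariant to the input row order
    for _, g in panel.sort_values(["person_id", "age"]).groupby(
            "person_id", sort=True):
        ages = g["age"].to_numpy(float)
        st = g["state"].to_numpy(int)
        for a in range(len(g) - 1):
            if st[a] == DEAD:
                continue
            counts[st[a] - 1, st[a + 1] - 1] += 1
            exposure[st[a] - 1] += ages[a + 1] - ages[a]
    beta = np.full(9, np.log(_CRUDE_RATE_FLOOR))
    for t, (r, s) in enumerate(TRANSITIONS):
        if not structure.active[t]:
            continue
        if exposure[r - 1] > 0 and counts[r - 1, s - 1] > 0:
            beta[t] = np.log(counts[r - 1, s - 1] / exposure[r - 1])
        else:
            logger.warning("transition %d->%d never observed; crude rate "
                           "floored at %.0e", r, s, _CRUDE_RATE_FLOOR)
        beta[t] = max(beta[t], np.log(_CRUDE_RATE_FLOOR))
    theta0 = np.zeros(structure.n_params)
    theta0[:structure.n_active] = beta[structure._act_idx]
    return theta0


def _central_gradient(f, x, step=1e-5):
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = step
        g[i] = (f(x + e) - f(x - e)) / (2 * step)
    return g


def _fd_hessian(f, x, step=1e-3):
    """Central finite-difference Hessian, symmetrized."""
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] + fm[i] - 2 * f0) / step ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = step
            ej[j] = step
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp + fmm + 2 * f0 - fp[i] - fm[i] - fp[j] - fm[j]
            ) / (2 * step ** 2)
    return 0.5 * (H + H.T)


class GompertzMultistateModel:
    """Four-state Gompertz multistate model for interval-censored panels.

    Parameters
    ----------
    panel : DataFrame with columns person_id, age, state, kind,
        gender01, education01 (the model-ready panel of
        :func:`hwle.states.build_panel`).
    spec : ModelSpecification (covariate set, tied slopes, grid step).
    zero_rate : iterable of (r, s) transitions forced to intensity zero
        (used by degenerate test models).
    centering_age : age at which baseline intensities are defined.
    """

    def __init__(self, panel: pd.DataFrame,
                 spec: ModelSpecification | None = None,
                 zero_rate=(), centering_age: float = 51.0):
        self.panel = panel
        self.spec = spec or ModelSpecification()
        active = np.ones(9, bool)
        for rs in zero_rate:
            idx = TRANSITIONS.index(tuple(rs))
            active[idx] = False
        self.structure = ParameterStructure(
            self.spec.covariate_columns, self.spec.tie_age_slopes,
            active, centering_age)
        self.intervals: PanelIntervals = compile_intervals(
            panel, self.spec.covariate_columns, self.spec.grid_step,
            centering_age)

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, covariate_set: str = "none",
                       grid_step: float = 0.5, tie_age_slopes: bool = False,
                       **kw) -> "GompertzMultistateModel":
        return cls(panel, ModelSpecification(covariate_set, tie_age_slopes,
                                             grid_step), **kw)

    def loglike(self, theta: np.ndarray) -> float:
        params = self.structure.unpack(theta)
        return total_log_likelihood(self.intervals, params)

    def initialize_parameters(self) -> np.ndarray:
        return initialize_parameters(self.panel, self.structure)

    def fit(self, start_params=None, maxiter: int = 500,
            gtol: float = 1e-5, ftol_rel: float = 1e-9,
            compute_cov: bool = True, warm_start: bool = True
            ) -> "GompertzMultistateResults":
        theta0 = (np.asarray(start_params, float) if start_params is not None
                  else self.initialize_parameters())
        ll0 = self.loglike(theta0)

        def negll(x):
            v = self.loglike(x)
            return np.inf if not np.isfinite(v) else -v

        st = self.structure
        if warm_start and start_params is None and st.n_xi > 1:
            # cheap first pass: baseline intensities only, slopes frozen at 0
            nb = st.n_active

            def negll_beta(b):
                x = theta0.copy()
                x[:nb] = b
                return negll(x)

            pre = optimize.minimize(
                negll_beta, theta0[:nb], method="L-BFGS-B",
                jac=lambda b: _central_gradient(negll_beta, b),
                options={"maxiter": 60, "ftol": 1e-8})
            theta0 = theta0.copy()
            theta0[:nb] = pre.x
            ll0 = max(ll0, -pre.fun)

        # the optimizer works on rescaled coordinates: one unit of an age
        # slope moves the log intensity by ~0.1 x 30 years, so slopes are
        # shrunk to put all coordinates on comparable scales
        scale = np.ones(st.n_params)
        scale[st.n_active:st.n_active + st.n_xi] = 0.1

        def negll_s(phi):
            return negll(phi * scale)

        res = optimize.minimize(
            negll_s, theta0 / scale, method="L-BFGS-B",
            jac=lambda x: _central_gradient(negll_s, x),
            options={"maxiter": maxiter, "gtol": gtol,
                     "ftol": ftol_rel, "maxls": 60, "maxcor": 25})
        theta = res.x * scale
        llf = -res.fun
        if llf < ll0 - 1e-8:  # never degrade the start
            theta, llf = theta0, ll0
        converged = bool(res.success)
        if not converged:
            logger.warning("optimizer did not converge: %s", res.message)

        cov = None
        cov_usable = False
        if compute_cov and converged:
            H = _fd_hessian(negll, theta)
            try:
                np.linalg.cholesky(H)
                cov = np.linalg.inv(H)
                cov = 0.5 * (cov + cov.T)
                cov_usable = True
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
                cov = 0.5 * (cov + cov.T)
                logger.warning("observed information singular or not positive "
                               "definite; covariance flagged unusable")
        return GompertzMultistateResults(
            structure=self.structure, params=theta, cov_params=cov,
            llf=float(llf), converged=converged, cov_usable=cov_usable,
            model=self, spec=self.spec,
            n_persons=self.intervals.n_persons,
            n_records=self.intervals.n_records,
            n_iter=int(res.get("nit", -1)), message=str(res.message))


@dataclass
class GompertzMultistateResults:
    """Fitted Gompertz multistate model."""

    structure: ParameterStructure
    params: np.ndarray
    cov_params: np.ndarray | None
    llf: float
    converged: bool
    cov_usable: bool
    model: GompertzMultistateModel | None = None
    spec: ModelSpecification = field(default_factory=ModelSpecification)
    n_persons: int = 0
    n_records: int = 0
    n_iter: int = -1
    message: str = ""

    @property
    def param_names(self) -> list[str]:
        return self.structure.names()

    @property
    def bse(self) -> np.ndarray:
        if not self.cov_usable:
            raise ValueError("covariance unusable; standard errors unavailable")
        return np.sqrt(np.clip(np.diag(self.cov_params), 0, None))

    def gompertz_params(self, theta=None) -> GompertzParams:
        return self.structure.unpack(self.params if theta is None else theta)

    def wald_intervals(self, level: float = 0.95) -> pd.DataFrame:
        """theta +/- z * se on the working (log/linear) scale."""
        se = self.bse
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame({
            "estimate": self.params, "se": se,
            "lower": self.params - z * se, "upper": self.params + z * se,
        }, index=self.param_names)

    def transition_probability(self, x1, x2, covariates=(), grid_step=None):
        from .transitions import transition_probability
        return transition_probability(
            self.gompertz_params(), x1, x2, covariates,
            grid_step if grid_step is not None else self.spec.grid_step)

    def summary(self) -> str:
        lines = [
            "Gompertz multistate model (4 states, 9 transitions)",
            f"  covariates:   {self.spec.covariate_set}",
            f"  persons:      {self.n_persons}   records: {self.n_records}",
            f"  log-lik:      {self.llf:.3f}",
            f"  converged:    {self.converged} ({self.message})",
        ]
        if self.cov_usable:
            tab = self.wald_intervals()
            lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        else:
            est = pd.Series(self.params, index=self.param_names)
            lines.append(est.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        se = (self.bse if self.cov_usable else
              np.full(self.params.size, np.nan))
        return {
            "parameters": [
                {"name": n, "estimate": float(v), "se": float(s)}
                for n, v, s in zip(self.param_names, self.params, se)],
            "covariance": (None if self.cov_params is None
                           else self.cov_params.tolist()),
            "loglik": self.llf,
            "converged": self.converged,
            "cov_usable": self.cov_usable,
            "covariate_set": self.spec.covariate_set,
            "grid_step": self.spec.grid_step,
            "tie_age_slopes": self.spec.tie_age_slopes,
            "centering_age": self.structure.x0,
            "active_transitions": [list(TRANSITIONS[t])
                                   for t in self.structure._act_idx],
            "n_persons": self.n_persons,
            "n_records": self.n_records,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, data: dict) -> "GompertzMultistateResults":
        spec = ModelSpecification(data["covariate_set"],
                                  data.get("tie_age_slopes", False),
                                  data.get("grid_step", 0.5))
        active = np.zeros(9, bool)
        for rs in data["active_transitions"]:
            active[TRANSITIONS.index(tuple(rs))] = True
        structure = ParameterStructure(spec.covariate_columns,
                                       spec.tie_age_slopes, active,
                                       data.get("centering_age", 51.0))
        cov = data.get("covariance")
        cov = None if cov is None else np.asarray(cov, float)
        return cls(structure=structure,
                   params=np.array([p["estimate"]
                                    for p in data["parameters"]]),
                   cov_params=cov, llf=float(data.get("loglik", np.nan)),
                   converged=bool(data.get("converged", False)),
                   cov_usable=bool(data.get("cov_usable", cov is not None)),
                   spec=spec, n_persons=data.get("n_persons", 0),
                   n_records=data.get("n_records", 0))

    @classmethod
    def load(cls, path) -> "GompertzMultistateResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def wald_intervals(fit: GompertzMultistateResults, level: float = 0.95
                   ) -> pd.DataFrame:
    """Module-level alias of :meth:`GompertzMultistateResults.wald_intervals`."""
    return fit.wald_intervals(level)
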