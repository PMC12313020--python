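"""Age-specific distribution over the three living states.

A multinomial logistic model of the observed living state on age
(centered at 51) and the analysis covariates, pooling all living
person-wave observations.  Its fitted probabilities at the starting age
are the weights of the marginal expectancies.  Reference state:
healthy-and-in-work.

The fit itself is delegated to :class:`statsmodels` MNLogit; this module
wraps it behind the package's Model/Results convention and exposes the
flat parameter vector + covariance needed by the simulation-based
confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .states import ALIVE_OBSERVATION
from .transitions import HEALTHY_WORKING, NOT_WORKING, UNHEALTHY_WORKING

#: maximum |coefficient| beyond which we declare (quasi-)separation
_SEPARATION_BOUND = 30.0

LIVING_STATES = (HEALTHY_WORKING, UNHEALTHY_WORKING, NOT_WORKING)


class PrevalenceFitError(RuntimeError):
    """The multinomial state-distribution model could not be fitted."""


class StatePrevalenceModel:
    """Multinomial logit of living state on centered age and covariates."""

    def __init__(self, panel: pd.DataFrame, covariate_columns=(),
                 centering_age: float = 51.0, include_age: bool = True):
        alive = panel[panel["kind"] == ALIVE_OBSERVATION]
        if len(alive) == 0:
            raise ValueError("panel has no living observations")
        missing = [s for s in LIVING_STATES
                   if not (alive["state"] == s).any()]
        if missing:
            raise PrevalenceFitError(
                f"living state(s) {missing} unobserved; collapse states or "
                "widen the data before fitting the state distribution")
        self.covariate_columns = tuple(covariate_columns)
        self.centering_age = float(centering_age)
        self.include_age = include_age
        # endog codes 0/1/2 with 0 = healthy-working (reference)
        self._endog = alive["state"].map(
            {HEALTHY_WORKING: 0, UNHEALTHY_WORKING: 1, NOT_WORKING: 2}
        ).to_numpy(int)
        cols = [np.ones(len(alive))]
        self._exog_names = ["const"]
        if include_age:
            cols.append(alive["age"].to_numpy(float) - self.centering_age)
            self._exog_names.append("agec")
        for c in self.covariate_columns:
            cols.append(alive[c].to_numpy(float))
            self._exog_names.append(c)
        self._exog = np.column_stack(cols)

    def fit(self, maxiter: int = 200) -> "StatePrevalenceResults":
        import warnings as _warnings
        mod = sm.MNLogit(self._endog, self._exog)
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = mod.fit(method="newton", maxiter=maxiter, disp=0)
        except np.linalg.LinAlgError as err:
            raise PrevalenceFitError(
                f"state-distribution fit failed (singular Hessian): {err}"
            ) from err
        if not res.mle_retvals.get("converged", False):
            raise PrevalenceFitError("state-distribution fit did not converge")
        p = np.asarray(res.params, float)
        if not np.isfinite(p).all() or np.abs(p).max() > _SEPARATION_BOUND:
            raise PrevalenceFitError(
                "state-distribution coefficients diverged; the data are "
                "(quasi-)separated in age or covariates")
        params = p  # (k, 2): eq 1 = UW, eq 2 = NW
        cov = np.asarray(res.cov_params(), float)
        return StatePrevalenceResults(
            params=params, cov_flat=cov, llf=float(res.llf),
            exog_names=list(self._exog_names),
            covariate_columns=self.covariate_columns,
            centering_age=self.centering_age, include_age=self.include_age,
            nobs=len(self._endog))


class StatePrevalenceResults:
    """Fitted multinomial state-distribution model.

    ``params`` has shape (k, 2): one column per non-reference state
    (unhealthy-working, not-working), rows ordered as ``exog_names``.
    ``cov_flat`` is the covariance of ``params.ravel(order="F")`` —
    equation-major, matching the statsmodels layout.
    """

    def __init__(self, params, cov_flat, llf, exog_names, covariate_columns,
                 centering_age, include_age=True, nobs=0):
        self.params = np.asarray(params, float)
        self.cov_flat = None if cov_flat is None else np.asarray(cov_flat, float)
        self.llf = llf
        self.exog_names = list(exog_names)
        self.covariate_columns = tuple(covariate_columns)
        self.centering_age = float(centering_age)
        self.include_age = include_age
        self.nobs = nobs

    @property
    def flat_params(self) -> np.ndarray:
        return self.params.ravel(order="F")

    def with_params(self, flat: np.ndarray) -> "StatePrevalenceResults":
        p = np.asarray(flat, float).reshape(self.params.shape, order="F")
        return StatePrevalenceResults(
            p, None, np.nan, self.exog_names, self.covariate_columns,
            self.centering_age, self.include_age, self.nobs)

    def _design_row(self, age: float, covariates=()) -> np.ndarray:
        z = np.asarray(covariates, float).reshape(-1)
        if z.size != len(self.covariate_columns):
            raise ValueError(
                f"expected {len(self.covariate_columns)} covariates, got {z.size}")
        row = [1.0]
        if self.include_age:
            row.append(float(age) - self.centering_age)
        return np.concatenate([row, z])

    def state_probabilities(self, age: float, covariates=()) -> np.ndarray:
        """Probabilities of (healthy-working, unhealthy-working, not-working)."""
        x = self._design_row(age, covariates)
        eta = np.concatenate([[0.0], x @ self.params])
        eta -= eta.max()
        p = np.exp(eta)
        return p / p.sum()

    def to_dict(self) -> dict:
        names = [f"{st}.{nm}" for st in ("unhealthy_working", "not_working")
                 for nm in self.exog_names]
        return {
            "parameters": [{"name": n, "estimate": float(v)}
                           for n, v in zip(names, self.flat_params)],
            "covariance": (None if self.cov_flat is None
                           else self.cov_flat.tolist()),
            "loglik": self.llf,
            "centering_age": self.centering_age,
            "include_age": self.include_age,
            "covariate_columns": list(self.covariate_columns),
            "nobs": self.nobs,
        }


def fit_state_distribution(panel: pd.DataFrame, covariate_columns=(),
                           centering_age: float = 51.0,
                           include_age: bool = True) -> StatePrevalenceResults:
    """Fit the multinomial state-distribution model on living observations."""
    return StatePrevalenceModel(panel, covariate_columns, centering_age,
                                include_age).fit()


def state_probabilities(results: StatePrevalenceResults, age: float,
                        covariates=()) -> np.ndarray:
    """Module-level alias of the results method."""
    return results.state_probabilities(age, covariates)
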