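"""Four-state space and Gompertz transition intensities.

The state space is the one used throughout the package:

    1  healthy and in work
    2  unhealthy and in work (work-limiting health problem, still working)
    3  not in work
    4  dead (absorbing)

All six transitions among the living states are permitted, plus death
from each living state: nine transitions in total.  Each permitted
transition (r, s) carries a Gompertz (log-linear in age) intensity

    q_rs(x, z) = exp(beta_rs + xi_rs * (x - x0) + gamma_rs . z)

where ``x0`` is a centering age (51 by default, the youngest entry age of
the cohorts) and ``z`` is a vector of 0/1 covariate indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._expm import expm_batch

#: Ordered state labels.
HEALTHY_WORKING, UNHEALTHY_WORKING, NOT_WORKING, DEAD = 1, 2, 3, 4

STATE_LABELS = {
    HEALTHY_WORKING: "healthy_working",
    UNHEALTHY_WORKING: "unhealthy_working",
    NOT_WORKING: "not_working",
    DEAD: "dead",
}

#: The nine permitted transitions, in the canonical parameter order.
TRANSITIONS: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 3), (1, 4),
    (2, 1), (2, 3), (2, 4),
    (3, 1), (3, 2), (3, 4),
)

TRANSITION_INDEX = {rs: k for k, rs in enumerate(TRANSITIONS)}

#: Index (within TRANSITIONS) of the death transition out of each living state.
DEATH_TRANSITION_OF = {1: TRANSITION_INDEX[(1, 4)],
                       2: TRANSITION_INDEX[(2, 4)],
                       3: TRANSITION_INDEX[(3, 4)]}

# Linear predictors are clipped at this value before exponentiation; it
# keeps the likelihood finite (and the optimizer recoverable) when a line
# search wanders into absurd territory.  exp(30) per year is far beyond
# any rate the data could support.
_LP_CLIP = 30.0


@dataclass(frozen=True)
class StateSpace:
    """The fixed four-state structure (exposed mostly for introspection)."""

    states: tuple[int, ...] = (1, 2, 3, 4)
    permitted_transitions: tuple[tuple[int, int], ...] = TRANSITIONS
    absorbing: int = DEAD

    def is_permitted(self, r: int, s: int) -> bool:
        return (r, s) in TRANSITION_INDEX


STATE_SPACE = StateSpace()


@dataclass
class GompertzParams:
    """Numeric parameter values of the nine-transition Gompertz model.

    Parameters
    ----------
    beta : (9,) log baseline intensities at the centering age.
    xi : (9,) age slopes (per year of age).
    gamma : (9, k) covariate log intensity ratios; ``k`` may be 0.
    active : (9,) bool; inactive transitions have intensity exactly 0
        regardless of ``beta`` (the "zero-rate flag").
    x0 : centering age in years.
    """

    beta: np.ndarray
    xi: np.ndarray
    gamma: np.ndarray
    active: np.ndarray = field(default_factory=lambda: np.ones(9, bool))
    x0: float = 51.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.xi = np.asarray(self.xi, float)
        self.gamma = np.atleast_2d(np.asarray(self.gamma, float))
        if self.gamma.shape[0] != 9:
            self.gamma = self.gamma.reshape(9, -1)
        self.active = np.asarray(self.active, bool)
        for name, arr in (("beta", self.beta), ("xi", self.xi),
                          ("gamma", self.gamma)):
            bad = ~np.isfinite(arr[self.active])
            if bad.any():
                tr = TRANSITIONS[int(np.nonzero(bad.reshape(bad.shape[0], -1).any(axis=-1) if arr.ndim > 1 else bad)[0][0])]
                raise ValueError(
                    f"non-finite {name} parameter for transition {tr[0]}->{tr[1]}")

    @property
    def n_covariates(self) -> int:
        return self.gamma.shape[1]

    def rates(self, age, z: Sequence[float] = ()) -> np.ndarray:
        """Intensities of the nine transitions at ``age`` for covariates ``z``.

        ``age`` may be scalar or an array; the result has shape
        ``age.shape + (9,)``.
        """
        age = np.asarray(age, float)
        z = np.asarray(z, float).reshape(-1)
        if z.size != self.n_covariates:
            raise ValueError(
                f"expected {self.n_covariates} covariates, got {z.size}")
        lp = self.beta + np.multiply.outer(age - self.x0, self.xi)
        if self.n_covariates:
            lp = lp + self.gamma @ z
        q = np.exp(np.clip(lp, -_LP_CLIP, _LP_CLIP))
        return np.where(self.active, q, 0.0)

    def intensity_matrix(self, age: float, z: Sequence[float] = ()) -> np.ndarray:
        """4x4 generator matrix Q at ``age``: row sums 0, dead row 0."""
        return build_intensity_matrix(self, age, z)

    def death_rates(self, age, z: Sequence[float] = ()) -> np.ndarray:
        """Death intensities from the three living states at ``age``."""
        q = self.rates(age, z)
        return q[..., [DEATH_TRANSITION_OF[1], DEATH_TRANSITION_OF[2],
                       DEATH_TRANSITION_OF[3]]]


def build_intensity_matrix(params: GompertzParams, age: float,
                           covariates: Sequence[float] = ()) -> np.ndarray:
    """Assemble the 4x4 transition intensity matrix at a given age.

    Off-diagonal entries are the Gompertz intensities of the permitted
    transitions (zero elsewhere); diagonal entries make each row sum to
    zero; the dead row is identically zero.
    """
    if not np.isfinite(age):
        raise ValueError("age must be finite")
    q = params.rates(float(age), covariates)
    Q = np.zeros((4, 4))
    for k, (r, s) in enumerate(TRANSITIONS):
        Q[r - 1, s - 1] = q[k]
    Q[np.arange(4), np.arange(4)] = -Q.sum(axis=1)
    return Q


def alive_generator(params: GompertzParams, ages, z=()) -> np.ndarray:
    """Stacked 3x3 living-state blocks of Q at each age in ``ages``.

    The block's diagonal includes the exit rate to death, so its matrix
    exponential is the living-to-living block of the full 4x4 transition
    probability matrix (death being absorbing).
    """
    q = params.rates(np.asarray(ages, float), z)  # (..., 9)
    A = np.zeros(q.shape[:-1] + (3, 3))
    for k, (r, s) in enumerate(TRANSITIONS):
        if s != DEAD:
            A[..., r - 1, s - 1] = q[..., k]
        A[..., r - 1, r - 1] -= q[..., k]
    return A


def grid_breakpoints(x1: float, x2: float, grid_step: float,
                     x0: float = 51.0) -> np.ndarray:
    """Partition of [x1, x2] anchored on the global grid x0 + k*grid_step.

    Anchoring the grid globally (rather than relative to x1) makes the
    piecewise-constant approximation satisfy Chapman-Kolmogorov exactly
    whenever the split point lies on the grid.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if x2 < x1:
        raise ValueError(f"x2={x2} earlier than x1={x1}")
    if x2 == x1:
        return np.array([x1])
    k1 = int(np.floor((x1 - x0) / grid_step + 1e-12)) + 1
    k2 = int(np.ceil((x2 - x0) / grid_step - 1e-12))
    inner = x0 + grid_step * np.arange(k1, k2)
    pts = np.concatenate(([x1], inner, [x2]))
    # guard against duplicates from floating-point coincidences
    keep = np.concatenate(([True], np.diff(pts) > 1e-12))
    return pts[keep]


def transition_probability(params: GompertzParams, x1: float, x2: float,
                           covariates: Sequence[float] = (),
                           grid_step: float = 0.5) -> np.ndarray:
    """4x4 matrix of P(state s at age x2 | state r at age x1).

    Age dependence is approximated as piecewise constant on the anchored
    grid, with intensities evaluated at the left endpoint of each cell;
    the matrix is the ordered product of cell-wise matrix exponentials.
    """
    pts = grid_breakpoints(x1, x2, grid_step, params.x0)
    if pts.size == 1:
        return np.eye(4)
    A = alive_generator(params, pts[:-1], covariates)
    E = expm_batch(A * np.diff(pts)[:, None, None])
    P3 = np.eye(3)
    for k in range(E.shape[0]):
        P3 = P3 @ E[k]
    P = np.zeros((4, 4))
    P[:3, :3] = P3
    P[:3, 3] = 1.0 - P3.sum(axis=1)
    P[3, 3] = 1.0
    return P
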