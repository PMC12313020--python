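"""Independent oracles used by the test suite.

These deliberately avoid the package's matrix-exponential code path:
transition probabilities are obtained by integrating the Kolmogorov
forward equations with a high-accuracy ODE solver over the same
piecewise-constant intensity function, and likelihood terms are rebuilt
from those ODE solutions.
"""

import numpy as np
from scipy.integrate import solve_ivp

from hwle.states import EXACT_DEATH
from hwle.transitions import DEAD, grid_breakpoints


def ode_transition_matrix(params, x1, x2, z=(), grid_step=0.5,
                          rtol=1e-11, atol=1e-13):
    """4x4 transition probability matrix via the forward equations.

    Integrates dP/du = P Q(u) segment by segment on the same anchored
    grid (intensities frozen at each segment's left endpoint) with an
    adaptive Runge-Kutta method at tight tolerances.
    """
    pts = grid_breakpoints(x1, x2, grid_step, params.x0)
    P = np.eye(4)
    for a, b in zip(pts[:-1], pts[1:]):
        Q = params.intensity_matrix(a, z)

        def rhs(_, y):
            return (y.reshape(4, 4) @ Q).ravel()

        sol = solve_ivp(rhs, (0.0, b - a), P.ravel(), method="DOP853",
                        rtol=rtol, atol=atol)
        P = sol.y[:, -1].reshape(4, 4)
    return P


def ode_log_likelihood(panel, params, grid_step=0.5, covariate_columns=()):
    """Panel log-likelihood rebuilt from ODE transition matrices."""
    total = 0.0
    for _, g in panel.groupby("person_id", sort=False):
        g = g.sort_values("age")
        rows = list(g.itertuples(index=False))
        for r1, r2 in zip(rows[:-1], rows[1:]):
            if r1.kind == EXACT_DEATH:
                continue
            z = tuple(getattr(r1, c) for c in covariate_columns)
            P = ode_transition_matrix(params, r1.age, r2.age, z, grid_step)
            if r2.kind == EXACT_DEATH or r2.state == DEAD:
                qd = params.death_rates(r2.age, z)
                total += np.log(P[r1.state - 1, :3] @ qd)
            else:
                total += np.log(P[r1.state - 1, r2.state - 1])
    return total
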