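import numpy as np
import pandas as pd
import pytest

from hwle.simulate import TruthConfig, default_params, generate_raw_records
from hwle.states import prepare_panel
from hwle.transitions import GompertzParams


def make_params(rates: dict, xi: dict | None = None, gamma=None,
                x0: float = 51.0) -> GompertzParams:
    """Build GompertzParams from {(r, s): rate-at-x0} dicts.

    Transitions not mentioned get the zero-rate flag.
    """
    from hwle.transitions import TRANSITIONS
    beta = np.zeros(9)
    xiv = np.zeros(9)
    active = np.zeros(9, bool)
    for rs, rate in rates.items():
        k = TRANSITIONS.index(tuple(rs))
        beta[k] = np.log(rate)
        active[k] = True
    for rs, slope in (xi or {}).items():
        xiv[TRANSITIONS.index(tuple(rs))] = slope
    g = np.zeros((9, 0)) if gamma is None else np.asarray(gamma, float)
    return GompertzParams(beta=beta, xi=xiv, gamma=g, active=active, x0=x0)


@pytest.fixture(scope="session")
def small_truth() -> TruthConfig:
    """A 240-person synthetic survey panel configuration."""
    return TruthConfig(cohort_sizes={"HRS": 80, "WB": 80, "EBB": 80},
                       seed=20260901, params=default_params(True))


@pytest.fixture(scope="session")
def small_raw(small_truth) -> pd.DataFrame:
    return generate_raw_records(small_truth)


@pytest.fixture(scope="session")
def small_panel(small_raw) -> pd.DataFrame:
    panel, _ = prepare_panel(small_raw)
    return panel


@pytest.fixture(scope="session")
def random_gompertz_sets():
    """50 random moderate Gompertz parameter sets (seeded)."""
    rng = np.random.default_rng(991)
    out = []
    for _ in range(50):
        beta = rng.uniform(np.log(0.005), np.log(0.5), 9)
        xi = rng.uniform(-0.1, 0.1, 9)
        out.append(GompertzParams(beta=beta, xi=xi, gamma=np.zeros((9, 0))))
    return out
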