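"""Synthetic HRS-like cohort panels from known true parameters.

This module is both the fixture generator for the rest of the package
and the microsimulation oracle for the expectancy integrals.  It
simulates exact continuous-time trajectories of the four-state Gompertz
process by thinning (rejection against a dominating constant rate per
one-year age band — the total exit intensity is a sum of exponentials in
age, hence convex, so its band maximum sits at an endpoint and
1.1 x max(endpoint totals) is a rigorous envelope), then observes them
the way the survey would: biennial interviews from a staggered entry age
in 51-61, exact death ages while under follow-up, non-informative
per-wave attrition, and survey fields (working, limitation, self-rated
health, weekly hours) back-derived from the underlying state.

Default parameter values are the package's stated synthetic world —
annual intensities at age 51 with Gompertz slopes chosen to reproduce
the broad features of US cohorts aged 51-80 (working-life expectancy
near 10 of 29 years, partial life expectancy near 24 years); see
docs/methods.md.  They are not estimates from any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import RAW_COLUMNS
from .transitions import DEAD, GompertzParams

#: per living state (0-based): indices into TRANSITIONS of its exits and
#: the 0-based destination codes (3 = dead)
_EXIT_TR = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8]])
_EXIT_DEST = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3]])

_ENVELOPE_MARGIN = 1.1

_SELF_RATED = np.array(["excellent", "very good", "good", "fair", "poor"])
_SELF_RATED_P = {
    0: np.array([0.25, 0.35, 0.30, 0.08, 0.02]),
    1: np.array([0.03, 0.10, 0.32, 0.35, 0.20]),
    2: np.array([0.10, 0.22, 0.33, 0.22, 0.13]),
}


def default_params(with_covariates: bool = True) -> GompertzParams:
    """The stated synthetic truth: annual intensities at age 51 + slopes.

    Calibrated once so the implied marginal expectancies over ages 51-80
    (healthy-working ~9.3, unhealthy-working ~1.1, working ~10.4, partial
    life expectancy ~23.5 years) sit in the range reported for US cohorts
    of this period; see docs/methods.md.
    """
    beta = np.log([0.04, 0.06, 0.002,    # from healthy-working: ->UW, ->NW, ->dead
                   0.35, 0.25, 0.010,    # from unhealthy-working
                   0.18, 0.02, 0.0075])  # from not-working
    xi = np.array([0.05, 0.055, 0.09,
                   -0.02, 0.04, 0.09,
                   -0.09, -0.08, 0.09])
    if with_covariates:
        # columns: (women, high education)
        gamma = np.array([
            [0.00, -0.10], [0.15, -0.15], [-0.35, -0.25],
            [0.00, 0.10], [0.10, -0.10], [-0.35, -0.25],
            [-0.25, 0.20], [-0.10, 0.10], [-0.35, -0.30],
        ])
    else:
        gamma = np.zeros((9, 0))
    return GompertzParams(beta=beta, xi=xi, gamma=gamma)


@dataclass
class TruthConfig:
    """Design of the synthetic cohort panel."""

    params: GompertzParams = field(default_factory=default_params)
    cohort_sizes: dict = field(default_factory=lambda: {
        "HRS": 1000, "WB": 1000, "EBB": 1000})
    entry_age_range: tuple = (51.0, 61.0)
    initial_distribution: tuple = (0.62, 0.08, 0.30)
    wave_spacing: float = 2.0
    max_waves: int = 15
    attrition: float = 0.03
    p_women: float = 0.53
    p_high_education: float = 0.45
    age_cap: float = 102.0
    seed: int | None = None

    def __post_init__(self) -> None:
        pi = np.asarray(self.initial_distribution, float)
        if not np.isclose(pi.sum(), 1.0) or (pi < 0).any():
            raise ValueError("initial state distribution must be a probability "
                             "vector over the three living states")
        if not 0.0 <= self.attrition < 1.0:
            raise ValueError("attrition probability must be in [0, 1)")


_COHORT_BANDS = {"HRS": (1936, 1941), "WB": (1942, 1947), "EBB": (1948, 1953)}


def _exit_rates(params: GompertzParams, state0: int, age, z) -> np.ndarray:
    q = params.rates(age, z)
    return q[..., _EXIT_TR[state0]]


def simulate_trajectory(params: GompertzParams, covariates, entry_age: float,
                        initial_state: int, rng: np.random.Generator,
                        age_cap: float = 102.0):
    """One exact continuous-time path: (jump ages, states), dead absorbing.

    ``initial_state`` is a living state label 1-3; the path ends at death
    or ``age_cap``.
    """
    z = np.asarray(covariates, float)
    times = [float(entry_age)]
    states = [int(initial_state)]
    t = float(entry_age)
    s0 = initial_state - 1
    while t < age_cap:
        lo = np.floor(t)
        hi = min(lo + 1.0, age_cap)
        q_lo = _exit_rates(params, s0, lo, z).sum()
        q_hi = _exit_rates(params, s0, hi, z).sum()
        lam = _ENVELOPE_MARGIN * max(q_lo, q_hi)
        if lam <= 0:
            t = hi
            continue
        t_cand = t + rng.exponential(1.0 / lam)
        if t_cand >= hi:
            t = hi
            continue
        t = t_cand
        q = _exit_rates(params, s0, t, z)
        qtot = q.sum()
        if qtot > lam * (1 + 1e-9):
            raise RuntimeError(
                "thinning envelope exceeded; intensities grow too fast within "
                "a one-year band — use a finer thinning envelope")
        if rng.uniform() < qtot / lam:
            dest = _EXIT_DEST[s0][rng.choice(3, p=q / qtot)]
            times.append(t)
            states.append(dest + 1)
            if dest + 1 == DEAD:
                break
            s0 = dest
    return np.asarray(times), np.asarray(states)


def state_at(times: np.ndarray, states: np.ndarray, age: float) -> int:
    """State of a simulated path at a given age (path must cover it)."""
    idx = np.searchsorted(times, age, side="right") - 1
    return int(states[max(idx, 0)])


def observe_panel(trajectories: list, truth: TruthConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Read simulated paths at biennial interview ages -> raw records.

    ``trajectories`` is a list of dicts with keys times, states,
    person_id, birth_year, entry_age, gender01, education01.  Attrition
    applies after each completed wave from the second on, so everyone
    responds at least twice; death ages are recorded (exit interview)
    only while the person is still under follow-up.
    """
    rows = []
    for tr in trajectories:
        times, states = tr["times"], tr["states"]
        death_age = float(times[-1]) if states[-1] == DEAD else None
        entry = tr["entry_age"]
        observed_death = None
        n_attended = 0
        for k in range(truth.max_waves):
            age_k = entry + truth.wave_spacing * k
            if age_k > truth.age_cap:
                break
            if death_age is not None and death_age <= age_k:
                observed_death = death_age
                break
            if n_attended >= 2 and rng.uniform() < truth.attrition:
                break
            st = state_at(times, states, age_k)
            working = "yes" if st in (1, 2) else "no"
            limited = ("yes" if st == 2 else
                       ("no" if st == 1 else
                        ("yes" if rng.uniform() < 0.35 else "no")))
            self_rated = str(rng.choice(_SELF_RATED, p=_SELF_RATED_P[st - 1]))
            if st in (1, 2):
                part_time = rng.uniform() < (0.08 if st == 1 else 0.15)
                hours = (round(rng.uniform(3, 14), 1) if part_time else
                         round(np.clip(rng.normal(40 if st == 1 else 34,
                                                  8 if st == 1 else 10),
                                       15, 80), 1))
            else:
                hours = np.nan
            rows.append((tr["person_id"], tr["birth_year"], k + 1,
                         age_k, working, hours, limited, self_rated,
                         np.nan, "women" if tr["gender01"] else "men",
                         "high" if tr["education01"] else "low", "no"))
            n_attended += 1
        if observed_death is not None and n_attended:
            # write the death age onto the person's rows
            for i in range(len(rows) - n_attended, len(rows)):
                rows[i] = rows[i][:8] + (observed_death,) + rows[i][9:]
    return pd.DataFrame(rows, columns=RAW_COLUMNS)


def generate_raw_records(truth: TruthConfig, seed: int | None = None
                         ) -> pd.DataFrame:
    """Simulate the full synthetic survey panel in the raw-record dialect."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    pi = np.asarray(truth.initial_distribution, float)
    k_cov = truth.params.n_covariates
    trajectories = []
    pid = 0
    for cohort, n in truth.cohort_sizes.items():
        lo, hi = _COHORT_BANDS[cohort]
        for _ in range(int(n)):
            pid += 1
            gender01 = int(rng.uniform() < truth.p_women)
            education01 = int(rng.uniform() < truth.p_high_education)
            z = np.array([gender01, education01], float)[:k_cov]
            entry = rng.uniform(*truth.entry_age_range)
            s0 = int(rng.choice(3, p=pi)) + 1
            times, states = simulate_trajectory(
                truth.params, z, entry, s0, rng, truth.age_cap)
            trajectories.append(dict(
                times=times, states=states, person_id=f"{cohort}-{pid:06d}",
                birth_year=int(rng.integers(lo, hi + 1)), entry_age=entry,
                gender01=gender01, education01=education01))
    return observe_panel(trajectories, truth, rng)


def microsim_expectancy(params: GompertzParams, initial_distribution,
                        age_window=(51.0, 80.0), n_trajectories: int = 200_000,
                        seed: int | None = None, covariates=()) -> dict:
    """Mean years per state within the window across simulated trajectories.

    The vectorized counterpart of :func:`simulate_trajectory` (same
    thinning construction); serves as the independent oracle for the
    expectancy integrals.  Returns mean years in each living state plus
    the dead state; the four sum to the window width exactly.
    """
    start, end = map(float, age_window)
    z = np.asarray(covariates, float)
    rng = np.random.default_rng(seed)
    n = int(n_trajectories)
    pi = np.asarray(initial_distribution, float)
    state = rng.choice(3, size=n, p=pi / pi.sum())
    t = np.full(n, start)
    alive = np.ones(n, bool)
    soj = np.zeros((n, 4))

    def qmat(ages):
        return params.rates(ages, z)  # (m, 9)

    band_lo = np.floor(start)
    while band_lo < end:
        band_hi = min(band_lo + 1.0, end)
        # envelope per state for this band
        q_ends = np.stack([qmat(np.array([band_lo])), qmat(np.array([band_hi]))])
        lam_state = _ENVELOPE_MARGIN * np.maximum(
            q_ends[0, 0][_EXIT_TR].sum(axis=1),
            q_ends[1, 0][_EXIT_TR].sum(axis=1))
        active = alive & (t < band_hi - 1e-12)
        while active.any():
            idx = np.nonzero(active)[0]
            lam = lam_state[state[idx]]
            with np.errstate(divide="ignore"):
                dt = rng.exponential(1.0, size=idx.size) / lam
            tn = np.minimum(t[idx] + dt, band_hi)
            soj[idx, state[idx]] += tn - t[idx]
            t[idx] = tn
            crossed = tn >= band_hi - 1e-12
            cand = idx[~crossed]
            if cand.size:
                q = qmat(t[cand])  # (m, 9)
                qex = np.take_along_axis(
                    q, _EXIT_TR[state[cand]], axis=1)  # (m, 3)
                qtot = qex.sum(axis=1)
                if np.any(qtot > lam_state[state[cand]] * (1 + 1e-9)):
                    raise RuntimeError(
                        "thinning envelope exceeded; use a finer envelope")
                u = rng.uniform(size=cand.size)
                acc = u < qtot / lam_state[state[cand]]
                hit = cand[acc]
                if hit.size:
                    cum = np.cumsum(qex[acc], axis=1)
                    v = rng.uniform(size=hit.size) * qtot[acc]
                    which = (v[:, None] > cum).sum(axis=1)
                    dest = _EXIT_DEST[state[hit], which]
                    died = dest == 3
                    state[hit] = np.where(died, state[hit], dest)
                    if died.any():
                        d = hit[died]
                        alive[d] = False
                        soj[d, 3] += end - t[d]
            active = alive & (t < band_hi - 1e-12)
        band_lo += 1.0
    means = soj.mean(axis=0)
    return {"healthy_working": means[0], "unhealthy_working": means[1],
            "not_working": means[2], "dead": means[3]}
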