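"""Intensity matrices, transition probabilities, likelihood terms.

Derived expectations come from closed forms (two-state and progressive
chains solved analytically) or from an independent ODE integration of
the Kolmogorov forward equations (tests/_oracles.py).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_params
from _oracles import ode_log_likelihood, ode_transition_matrix

from hwle.likelihood import (LikelihoodUnderflowWarning, compile_intervals,
                             interval_contribution, total_log_likelihood)
from hwle.states import PanelRecord, EXACT_DEATH
from hwle.transitions import (GompertzParams, TRANSITIONS,
                              build_intensity_matrix, transition_probability)


def panel_frame(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "age", "state", "kind",
                       "gender01", "education01"])


class TestIntensityMatrix:
    def test_all_rates_zero(self):
        p = make_params({})  # every transition carries the zero-rate flag
        assert np.allclose(build_intensity_matrix(p, 60.0), 0.0)

    def test_direct_evaluation_at_center(self):
        p = make_params({(1, 3): 0.2})
        Q = build_intensity_matrix(p, 51.0)
        assert Q[0, 2] == pytest.approx(0.2)
        assert Q[0, 0] == pytest.approx(-0.2)

    def test_gompertz_age_slope(self):
        p = make_params({(1, 3): 0.2}, xi={(1, 3): 0.1})
        Q = build_intensity_matrix(p, 61.0)
        assert Q[0, 2] == pytest.approx(0.2 * np.e, rel=1e-12)

    def test_structure_invariants(self):
        rng = np.random.default_rng(3)
        p = GompertzParams(beta=rng.uniform(-4, -1, 9),
                           xi=rng.uniform(-0.1, 0.1, 9),
                           gamma=np.zeros((9, 0)))
        Q = build_intensity_matrix(p, 70.0)
        off = Q[~np.eye(4, dtype=bool)]
        assert (off >= 0).all()
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert np.allclose(Q[3], 0)

    def test_nonfinite_parameter_names_transition(self):
        with pytest.raises(ValueError, match="2->3"):
            beta = np.zeros(9)
            beta[4] = np.nan
            GompertzParams(beta=beta, xi=np.zeros(9), gamma=np.zeros((9, 0)))


class TestTransitionProbability:
    def test_zero_generator_gives_identity(self):
        p = make_params({})
        assert np.allclose(transition_probability(p, 51, 80), np.eye(4))

    def test_two_state_closed_form(self):
        # alive -> dead at constant rate 0.05 over 10 years
        p = make_params({(1, 4): 0.05})
        P = transition_probability(p, 51, 61)
        assert P[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert P[0, 3] == pytest.approx(1 - np.exp(-0.5), abs=1e-12)

    def test_progressive_chain_closed_form(self):
        # 1 -> 2 -> 3 with both rates 0.1 over 5 years
        p = make_params({(1, 2): 0.1, (2, 3): 0.1})
        P = transition_probability(p, 51, 56)
        expected = 1 - np.exp(-0.5) * (1 + 0.5)
        assert P[0, 2] == pytest.approx(expected, abs=1e-12)

    def test_x2_before_x1_errors(self):
        p = make_params({(1, 4): 0.05})
        with pytest.raises(ValueError):
            transition_probability(p, 61, 51)

    def test_identity_at_equal_ages(self):
        p = make_params({(1, 2): 0.3})
        assert np.allclose(transition_probability(p, 60, 60), np.eye(4))

    def test_row_stochastic_on_random_sets(self, random_gompertz_sets):
        for p in random_gompertz_sets[:10]:
            P = transition_probability(p, 51, 75, grid_step=0.5)
            assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-10)

    def test_chapman_kolmogorov_on_nested_grid(self, random_gompertz_sets):
        for p in random_gompertz_sets[:10]:
            P13 = transition_probability(p, 51.3, 70.0, grid_step=0.5)
            # split point on the anchored grid -> exact factorization
            P12 = transition_probability(p, 51.3, 60.0, grid_step=0.5)
            P23 = transition_probability(p, 60.0, 70.0, grid_step=0.5)
            assert np.allclose(P13, P12 @ P23, atol=1e-8)

    def test_agrees_with_ode_oracle(self, random_gompertz_sets):
        for p in random_gompertz_sets[:8]:
            P = transition_probability(p, 52.0, 68.0, grid_step=0.5)
            P_ode = ode_transition_matrix(p, 52.0, 68.0, grid_step=0.5)
            assert np.abs(P - P_ode).max() < 1e-6

    def test_monotone_mortality(self):
        base = make_params({(1, 2): 0.1, (2, 1): 0.1, (1, 4): 0.01,
                            (2, 4): 0.02})
        surv0 = transition_probability(base, 51, 75)[0, :3].sum()
        for death in [(1, 4), (2, 4)]:
            bumped = make_params({(1, 2): 0.1, (2, 1): 0.1,
                                  (1, 4): 0.01 * (2 if death == (1, 4) else 1),
                                  (2, 4): 0.02 * (2 if death == (2, 4) else 1)})
            assert transition_probability(bumped, 51, 75)[0, :3].sum() < surv0


class TestIntervalContribution:
    def test_same_state_zero_rates(self):
        p = make_params({})
        r1 = PanelRecord("a", 52.0, 1)
        r2 = PanelRecord("a", 54.0, 1)
        assert interval_contribution(r1, r2, p) == pytest.approx(0.0)

    def test_impossible_path_is_minus_inf(self):
        p = make_params({})
        r1 = PanelRecord("a", 52.0, 1)
        r2 = PanelRecord("a", 54.0, 3)
        with pytest.warns(LikelihoodUnderflowWarning):
            val = interval_contribution(r1, r2, p)
        assert val == -np.inf

    def test_exact_death_closed_form(self):
        # single living state, constant death rate 0.05, death 2y later:
        # log(exp(-0.1) * 0.05)
        p = make_params({(1, 4): 0.05})
        r1 = PanelRecord("a", 60.0, 1)
        r2 = PanelRecord("a", 62.0, 4, EXACT_DEATH)
        expected = -0.1 + np.log(0.05)
        assert interval_contribution(r1, r2, p) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(-3.0957, abs=1e-4)


class TestTotalLogLikelihood:
    def test_two_waves_same_state_zero_rates(self):
        p = make_params({})
        panel = panel_frame([("a", 52, 1, "alive_observation", 0, 0),
                             ("a", 54, 1, "alive_observation", 0, 0)])
        assert total_log_likelihood(panel, p) == pytest.approx(0.0)

    def test_additive_over_persons(self, random_gompertz_sets):
        p = random_gompertz_sets[0]
        rows_a = [("a", 52, 1, "alive_observation", 0, 0),
                  ("a", 54, 2, "alive_observation", 0, 0),
                  ("a", 56.4, 4, EXACT_DEATH, 0, 0)]
        rows_b = [("b", 53, 3, "alive_observation", 0, 0),
                  ("b", 55, 1, "alive_observation", 0, 0)]
        ll_a = total_log_likelihood(panel_frame(rows_a), p)
        ll_b = total_log_likelihood(panel_frame(rows_b), p)
        ll_ab = total_log_likelihood(panel_frame(rows_a + rows_b), p)
        assert ll_ab == pytest.approx(ll_a + ll_b, rel=1e-12)

    def test_empty_panel_errors(self):
        p = make_params({(1, 2): 0.1})
        with pytest.raises(ValueError):
            total_log_likelihood(panel_frame([]), p)

    def test_numba_and_numpy_paths_agree(self, small_panel,
                                         random_gompertz_sets):
        from hwle.likelihood import HAVE_NUMBA
        if not HAVE_NUMBA:
            pytest.skip("numba unavailable; only one path exists")
        p = random_gompertz_sets[1]
        iv = compile_intervals(small_panel, (), 0.5)
        a = total_log_likelihood(iv, p, use_numba=True)
        b = total_log_likelihood(iv, p, use_numba=False)
        assert a == pytest.approx(b, rel=1e-10)

    def test_agrees_with_ode_oracle_on_small_panel(self, small_panel):
        sub_ids = small_panel["person_id"].unique()[:12]
        sub = small_panel[small_panel["person_id"].isin(sub_ids)]
        p = make_params(
            {rs: v for rs, v in zip(TRANSITIONS,
                                    [0.05, 0.1, 0.01, 0.2, 0.2, 0.02,
                                     0.08, 0.02, 0.015])},
            xi={rs: x for rs, x in zip(TRANSITIONS,
                                       [0.05, 0.06, 0.08, -0.02, 0.04,
                                        0.08, -0.1, -0.08, 0.08])})
        ll = total_log_likelihood(sub, p)
        ll_ode = ode_log_likelihood(sub, p)
        assert ll == pytest.approx(ll_ode, abs=1e-6)

    def test_invariant_to_person_relabeling_and_batching(self, small_panel,
                                                         random_gompertz_sets):
        p = random_gompertz_sets[2]
        ll = total_log_likelihood(small_panel, p)
        relabeled = small_panel.copy()
        mapping = {pid: f"z{i}" for i, pid in
                   enumerate(small_panel["person_id"].unique()[::-1])}
        relabeled["person_id"] = relabeled["person_id"].map(mapping)
        assert total_log_likelihood(relabeled, p) == pytest.approx(
            ll, rel=1e-10)
        ids = small_panel["person_id"].unique()
        half = set(ids[: len(ids) // 2])
        b1 = small_panel[small_panel["person_id"].isin(half)]
        b2 = small_panel[~small_panel["person_id"].isin(half)]
        assert (total_log_likelihood(b1, p) + total_log_likelihood(b2, p)
                == pytest.approx(ll, rel=1e-10))

    def test_gap_interval_spans_doubled_wave(self):
        """A skipped wave yields one likelihood term over the doubled gap."""
        p = make_params({(1, 3): 0.1, (3, 1): 0.05, (1, 4): 0.01,
                         (3, 4): 0.02}, xi={(1, 3): 0.05})
        panel = panel_frame([("g", 52, 1, "alive_observation", 0, 0),
                             ("g", 56, 3, "alive_observation", 0, 0)])
        ll = total_log_likelihood(panel, p)
        P_ode = ode_transition_matrix(p, 52, 56, grid_step=0.5)
        assert ll == pytest.approx(np.log(P_ode[0, 2]), abs=1e-8)


@given(x1=st.floats(51, 75), dx=st.floats(0.1, 10))
@settings(max_examples=30, deadline=None)
def test_row_sums_property(x1, dx):
    """Row-stochasticity holds for arbitrary windows (property test)."""
    p = make_params({(1, 2): 0.1, (2, 3): 0.2, (3, 1): 0.05, (1, 4): 0.02,
                     (2, 4): 0.05, (3, 4): 0.03}, xi={(1, 4): 0.09})
    P = transition_probability(p, x1, x1 + dx)
    assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
    assert np.all(P >= -1e-12)
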