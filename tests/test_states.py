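"""State classification, cohort assignment, eligibility filtering, panel build."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hwle.states import (InconsistentRecordError, EmptyPanelError,
                         RAW_COLUMNS, assign_cohort, build_panel,
                         classify_state, classify_state_alternative,
                         filter_eligibility)


def raw_frame(rows):
    """rows: list of dicts with partial fields; missing ones become NaN."""
    base = {c: np.nan for c in RAW_COLUMNS}
    return pd.DataFrame([{**base, **r} for r in rows])


def person_rows(pid, ages, working="yes", limited="no", birth_year=1940,
                gender="men", education="low", **extra):
    rows = []
    for w, a in enumerate(ages, start=1):
        rows.append(dict(person_id=pid, birth_year=birth_year, wave=w,
                         interview_age=a, working=working,
                         health_limited=limited, gender=gender,
                         education=education, is_spouse="no", **extra))
    return rows


class TestClassifyState:
    @pytest.mark.parametrize("working,limited,dead,expected", [
        ("yes", "no", False, 1),
        ("yes", "yes", False, 2),
        ("no", "yes", False, 3),   # not in work regardless of health
        ("no", "no", False, 3),
        ("no", None, False, 3),
        (None, None, True, 4),     # dead overrides everything
        (None, "no", False, None),   # missing working -> non-classifiable
        ("yes", None, False, None),  # working but limitation missing
    ])
    def test_main_rule(self, working, limited, dead, expected):
        assert classify_state(working, limited, dead) == expected

    def test_partition_of_valid_domain(self):
        """The three living outcomes partition working x limitation."""
        outcomes = {classify_state(w, l) for w in ("yes", "no")
                    for l in ("yes", "no")}
        assert outcomes == {1, 2, 3}

    @pytest.mark.parametrize("working,self_rated,hours,health,hrs,expected", [
        ("yes", "good", 40, "self_rated", "any", 1),
        ("yes", "excellent", 40, "self_rated", "any", 1),
        ("yes", "very good", 40, "self_rated", "any", 1),
        ("yes", "fair", 40, "self_rated", "any", 2),
        ("yes", "poor", 40, "self_rated", "any", 2),
        ("yes", "fair", 10, "self_rated", "min15", 3),  # <15h => not working
        ("yes", "fair", 15, "self_rated", "any", 2),    # 15 is not "less than 15"
        ("yes", "fair", 15, "self_rated", "min15", 2),
        ("no", "excellent", np.nan, "self_rated", "any", 3),
        ("yes", "weird", 40, "self_rated", "any", None),  # unknown category
        ("yes", None, 40, "self_rated", "any", None),
        ("yes", "good", None, "self_rated", "min15", None),  # hours demanded
    ])
    def test_alternative_rules(self, working, self_rated, hours, health, hrs,
                               expected):
        got = classify_state_alternative(working, self_rated, hours,
                                         health_rule=health, hours_rule=hrs)
        assert got == expected

    def test_min15_with_limitation_rule(self):
        assert classify_state_alternative(
            "yes", None, 10, health_rule="limitation", hours_rule="min15",
            health_limited="yes") == 3

    def test_unknown_rule_raises(self):
        with pytest.raises(ValueError):
            classify_state_alternative("yes", "good", 40, health_rule="bogus")


class TestAssignCohort:
    @pytest.mark.parametrize("year,expected", [
        (1945, "WB"), (1933, None), (1936, "HRS"), (1941, "HRS"),
        (1942, "WB"), (1947, "WB"), (1948, "EBB"), (1953, "EBB"),
        (1935, None), (1954, None), (1900, None),
    ])
    def test_bands(self, year, expected):
        assert assign_cohort(year) == expected

    def test_bands_disjoint_contiguous(self):
        labels = [assign_cohort(y) for y in range(1936, 1954)]
        assert None not in labels
        assert [labels[0], labels[6], labels[12]] == ["HRS", "WB", "EBB"]


class TestFilterEligibility:
    def test_single_wave_person_removed(self):
        df = raw_frame(person_rows("a", [52]) + person_rows("b", [52, 54]))
        kept, log = filter_eligibility(df)
        assert set(kept["person_id"]) == {"b"}
        assert log["fewer_than_two_waves_persons"] == 1

    def test_spouse_rows_under_51(self):
        rows = person_rows("s", [49, 53, 55])
        for r in rows:
            r["is_spouse"] = "yes"
        kept, log = filter_eligibility(raw_frame(rows))
        assert log["spouse_rows_under_51"] == 1
        assert sorted(kept["interview_age"]) == [53, 55]

    def test_no_rule_triggered(self):
        df = raw_frame(person_rows("ok", list(range(52, 70, 2))))
        kept, log = filter_eligibility(df)
        assert len(kept) == 9
        assert log["output_persons"] == 1

    def test_missing_covariates_and_cohort(self):
        df = raw_frame(
            person_rows("nocov", [52, 54], gender=None)
            + person_rows("oldc", [58, 60], birth_year=1933)
            + person_rows("ok", [52, 54]))
        kept, log = filter_eligibility(df)
        assert set(kept["person_id"]) == {"ok"}
        assert log["excluded_cohort_persons"] == 1
        assert log["missing_gender_education_persons"] == 1

    def test_person_level_counts_sum(self):
        df = raw_frame(
            person_rows("a", [52]) + person_rows("b", [52, 54])
            + person_rows("c", [52, 54], birth_year=1920)
            + person_rows("d", [52, 54], education=None))
        kept, log = filter_eligibility(df)
        removed = (log["input_persons"] - log["output_persons"])
        assert removed == (log["excluded_cohort_persons"]
                           + log["missing_gender_education_persons"]
                           + log["fewer_than_two_waves_persons"])

    def test_idempotent(self):
        df = raw_frame(
            person_rows("a", [52]) + person_rows("b", [52, 54, 56])
            + person_rows("c", [49, 53], birth_year=1950))
        once, _ = filter_eligibility(df)
        twice, log2 = filter_eligibility(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))
        assert log2["spouse_rows_under_51"] == 0

    def test_single_wave_with_observed_death_kept(self):
        """An exit interview counts as the second usable observation."""
        df = raw_frame(person_rows("d", [52], death_age=53.1)
                       + person_rows("ok", [52, 54]))
        kept, log = filter_eligibility(df)
        assert set(kept["person_id"]) == {"d", "ok"}
        panel = build_panel(kept)
        assert (panel.groupby("person_id").size() >= 2).all()

    def test_two_unusable_waves_do_not_qualify(self):
        # two waves whose states cannot be classified -> person removed
        df = raw_frame(person_rows("u", [52, 54], working=None))
        with pytest.raises(EmptyPanelError):
            filter_eligibility(df)

    def test_empty_result_names_dominant_rule(self):
        df = raw_frame(person_rows("x", [52, 54], birth_year=1925)
                       + person_rows("y", [52, 54], birth_year=1960))
        with pytest.raises(EmptyPanelError, match="excluded_cohort"):
            filter_eligibility(df)

    @given(st.lists(st.tuples(st.integers(1930, 1960),
                              st.integers(1, 4),
                              st.booleans()),
                    min_size=1, max_size=8))
    @settings(max_examples=25, deadline=None)
    def test_idempotence_property(self, spec):
        rows = []
        for i, (by, nwaves, has_cov) in enumerate(spec):
            rows += person_rows(
                f"p{i}", [52 + 2 * k for k in range(nwaves)], birth_year=by,
                gender="men" if has_cov else None)
        df = raw_frame(rows)
        try:
            once, _ = filter_eligibility(df)
        except EmptyPanelError:
            return
        twice, _ = filter_eligibility(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))


class TestBuildPanel:
    def test_death_appended(self):
        rows = person_rows("d", [52, 54, 56], death_age=57.3)
        panel = build_panel(raw_frame(rows))
        assert len(panel) == 4
        assert panel.iloc[-1]["kind"] == "exact_death"
        assert panel.iloc[-1]["age"] == 57.3
        assert panel.iloc[-1]["state"] == 4

    def test_censored_person(self):
        panel = build_panel(raw_frame(person_rows("c", [52, 54, 56])))
        assert len(panel) == 3
        assert (panel["kind"] == "alive_observation").all()

    def test_gap_spanned_when_wave_unclassifiable(self):
        rows = person_rows("g", [52, 54, 56])
        rows[1]["working"] = None  # middle wave unusable
        panel = build_panel(raw_frame(rows))
        assert list(panel["age"]) == [52, 56]

    def test_death_before_interview_is_hard_error(self):
        rows = person_rows("bad", [52, 54, 56], death_age=55.0)
        with pytest.raises(InconsistentRecordError):
            build_panel(raw_frame(rows))

    def test_covariate_coding(self):
        rows = person_rows("w", [52, 54], gender="women", education="high")
        panel = build_panel(raw_frame(rows))
        assert (panel["gender01"] == 1).all()
        assert (panel["education01"] == 1).all()
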