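"""Turn raw survey panel rows into model-ready state sequences.

Raw records are one row per person-wave in the dialect of the Health and
Retirement Study style of panel: biennial interviews, self-reported work
and health, exact death ages from exit interviews.  This module

* classifies each observation into the four analysis states
  (healthy-and-in-work, unhealthy-and-in-work, not-in-work, dead),
  including the sensitivity-analysis variants (self-rated health instead
  of work limitation; a >=15 hours/week employment threshold);
* assigns the three birth cohorts (HRS 1936-1941, WB 1942-1947,
  EBB 1948-1953);
* applies the eligibility filters (at least two classifiable waves,
  valid gender and education, spouse rows before age 51 dropped,
  out-of-range cohorts dropped), with a per-rule exclusion log;
* builds the model-ready panel: interval-censored living observations
  plus exact-death records, implicitly right-censored at the last living
  observation otherwise.

Raw-record CSV header::

    person_id,birth_year,wave,interview_age,working,hours_per_week,
    health_limited,self_rated,death_age,gender,education,is_spouse

``working``, ``health_limited`` and ``is_spouse`` take ``yes``/``no``;
``gender`` takes ``men``/``women``; ``education`` takes ``low``/``high``;
``self_rated`` one of excellent/very good/good/fair/poor.  Missing values
are empty fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .transitions import DEAD, HEALTHY_WORKING, NOT_WORKING, UNHEALTHY_WORKING

logger = logging.getLogger(__name__)

RAW_COLUMNS = [
    "person_id", "birth_year", "wave", "interview_age", "working",
    "hours_per_week", "health_limited", "self_rated", "death_age",
    "gender", "education", "is_spouse",
]

PANEL_COLUMNS = ["person_id", "age", "state", "kind", "gender01", "education01"]

GOOD_SELF_RATED = {"excellent", "very good", "good"}
POOR_SELF_RATED = {"fair", "poor"}

COHORTS = {"HRS": (1936, 1941), "WB": (1942, 1947), "EBB": (1948, 1953)}

ALIVE_OBSERVATION = "alive_observation"
EXACT_DEATH = "exact_death"
RIGHT_CENSORED = "right_censored"


class InconsistentRecordError(ValueError):
    """A record contradicts the panel structure (e.g. death before an interview)."""


class EmptyPanelError(ValueError):
    """Eligibility filtering removed everyone."""


@dataclass(frozen=True)
class CovariateProfile:
    """0/1 covariate coding: men and low education are the references."""

    gender01: int = 0   # 1 = women
    education01: int = 0  # 1 = high education

    def __post_init__(self) -> None:
        if self.gender01 not in (0, 1) or self.education01 not in (0, 1):
            raise ValueError("covariate indicators must be exactly 0 or 1")


@dataclass(frozen=True)
class PanelRecord:
    """One model-ready observation of one person."""

    person_id: object
    age: float
    state: int
    kind: str = ALIVE_OBSERVATION
    gender01: int = 0
    education01: int = 0


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or \
        (isinstance(v, str) and v.strip() == "") or v is pd.NA


def _yesno(v):
    if _is_missing(v):
        return None
    s = str(v).strip().lower()
    if s in ("yes", "y", "1", "true"):
        return True
    if s in ("no", "n", "0", "false"):
        return False
    return None


def classify_state(working, health_limited, dead: bool = False):
    """Main-analysis state classification.

    dead -> 4; working without limitation -> 1; working with limitation
    -> 2; not working -> 3 (whatever the health report).  Returns ``None``
    (non-classifiable) when a needed field is missing.
    """
    if dead:
        return DEAD
    w = _yesno(working)
    if w is None:
        return None
    if not w:
        return NOT_WORKING
    lim = _yesno(health_limited)
    if lim is None:
        return None
    return UNHEALTHY_WORKING if lim else HEALTHY_WORKING


def classify_state_alternative(working, self_rated, hours,
                               health_rule: str = "self_rated",
                               hours_rule: str = "any",
                               health_limited=None, dead: bool = False):
    """State classification under the sensitivity-analysis rules.

    ``health_rule``: ``limitation`` (work-limiting health problem) or
    ``self_rated`` (fair/poor self-rated health counts as unhealthy).
    ``hours_rule``: ``any`` or ``min15`` (less than 15 hours/week counts
    as not working; exactly 15 still counts as working).
    """
    if health_rule not in ("limitation", "self_rated"):
        raise ValueError(f"unknown health_rule {health_rule!r}")
    if hours_rule not in ("any", "min15"):
        raise ValueError(f"unknown hours_rule {hours_rule!r}")
    if dead:
        return DEAD
    w = _yesno(working)
    if w is None:
        return None
    if w and hours_rule == "min15":
        if _is_missing(hours):
            return None
        if float(hours) < 15.0:
            w = False
    if not w:
        return NOT_WORKING
    if health_rule == "limitation":
        lim = _yesno(health_limited)
        if lim is None:
            return None
        return UNHEALTHY_WORKING if lim else HEALTHY_WORKING
    if _is_missing(self_rated):
        return None
    cat = str(self_rated).strip().lower()
    if cat in GOOD_SELF_RATED:
        return HEALTHY_WORKING
    if cat in POOR_SELF_RATED:
        return UNHEALTHY_WORKING
    return None


def _classify_frame(df: pd.DataFrame, health_rule: str, hours_rule: str) -> pd.Series:
    """Vector-ish classification of the living rows of a raw-record frame."""
    out = []
    for row in df.itertuples(index=False):
        out.append(classify_state_alternative(
            row.working, getattr(row, "self_rated", None),
            getattr(row, "hours_per_week", None),
            health_rule=health_rule, hours_rule=hours_rule,
            health_limited=getattr(row, "health_limited", None)))
    return pd.Series(out, index=df.index, dtype=object)


def assign_cohort(birth_year):
    """Birth cohort label, or ``None`` for years outside the study bands."""
    if _is_missing(birth_year):
        return None
    y = int(birth_year)
    for label, (lo, hi) in COHORTS.items():
        if lo <= y <= hi:
            return label
    return None


def filter_eligibility(records: pd.DataFrame,
                       health_rule: str = "limitation",
                       hours_rule: str = "any"
                       ) -> tuple[pd.DataFrame, dict]:
    """Apply the study's eligibility filters; return kept rows + exclusion log.

    Row-level rule (counted in rows): spouse interviews before age 51.
    Person-level rules (counted in persons): excluded birth cohort,
    missing gender or education, fewer than two classifiable waves.
    The operation is idempotent.
    """
    df = records.copy()
    n_persons_in = df["person_id"].nunique()
    log: dict[str, int] = {"input_persons": n_persons_in,
                           "input_rows": len(df)}

    spouse = df["is_spouse"].map(lambda v: bool(_yesno(v))) if "is_spouse" in df else False
    under51 = df["interview_age"] < 51
    drop_rows = spouse & under51
    log["spouse_rows_under_51"] = int(drop_rows.sum())
    df = df[~drop_rows]

    cohort = df.groupby("person_id")["birth_year"].first().map(assign_cohort)
    bad_cohort = set(cohort[cohort.isna()].index)
    log["excluded_cohort_persons"] = len(bad_cohort)
    df = df[~df["person_id"].isin(bad_cohort)]

    def _has_cov(g):
        return (g["gender"].map(lambda v: not _is_missing(v)).any()
                and g["education"].map(lambda v: not _is_missing(v)).any())

    cov_ok = df.groupby("person_id", sort=False).apply(_has_cov, include_groups=False) \
        if len(df) else pd.Series(dtype=bool)
    bad_cov = set(cov_ok[~cov_ok].index)
    log["missing_gender_education_persons"] = len(bad_cov)
    df = df[~df["person_id"].isin(bad_cov)]

    if len(df):
        states = _classify_frame(df, health_rule, hours_rule)
        n_class = states.notna().groupby(df["person_id"]).sum()
        # an observed death (exit interview) counts as the second usable
        # observation: the likelihood needs one transition interval, and
        # dropping wave-1 decedents would select the sample on survival
        has_death = df["death_age"].notna().groupby(df["person_id"]).any()
        usable = n_class + has_death.astype(int)
        too_few = set(usable[(usable < 2) | (n_class < 1)].index)
    else:
        too_few = set()
    log["fewer_than_two_waves_persons"] = len(too_few)
    df = df[~df["person_id"].isin(too_few)]

    log["output_persons"] = df["person_id"].nunique()
    log["output_rows"] = len(df)
    if len(df) == 0 and len(records) > 0:
        person_rules = ["excluded_cohort_persons",
                        "missing_gender_education_persons",
                        "fewer_than_two_waves_persons"]
        dominant = max(person_rules, key=lambda k: log[k])
        raise EmptyPanelError(
            f"all persons excluded; dominant rule: {dominant} ({log[dominant]})")
    return df.reset_index(drop=True), log


def _first_valid(series: pd.Series, mapping: dict):
    for v in series:
        if not _is_missing(v):
            key = str(v).strip().lower()
            if key in mapping:
                return mapping[key]
    return None


def build_panel(records: pd.DataFrame,
                health_rule: str = "limitation",
                hours_rule: str = "any") -> pd.DataFrame:
    """Build the model-ready panel from (already filtered) raw records.

    One ``alive_observation`` row per classifiable wave, one
    ``exact_death`` row per decedent at the exact death age.  Waves with
    non-classifiable states are skipped, so the surrounding interval
    spans the gap.  Persons last seen alive are implicitly
    right-censored at their last observation.
    """
    rows = []
    n_dropped = 0
    for pid, g in records.groupby("person_id", sort=False):
        g = g.sort_values("interview_age")
        ages = g["interview_age"].to_numpy(float)
        if len(ages) > 1 and not np.all(np.diff(ages) > 0):
            raise InconsistentRecordError(
                f"person {pid}: interview ages not strictly increasing")
        gender01 = _first_valid(g["gender"], {"men": 0, "women": 1})
        education01 = _first_valid(g["education"], {"low": 0, "high": 1})
        states = _classify_frame(g, health_rule, hours_rule)
        death_age = g["death_age"].dropna()
        death_age = float(death_age.iloc[0]) if len(death_age) else None
        if death_age is not None and death_age < ages.max() - 1e-9:
            raise InconsistentRecordError(
                f"person {pid}: death age {death_age} earlier than an interview")
        kept = 0
        for age, st in zip(ages, states):
            if st is None or st == DEAD:
                n_dropped += st is None
                continue
            rows.append((pid, float(age), int(st), ALIVE_OBSERVATION,
                         gender01 or 0, education01 or 0))
            kept += 1
        if death_age is not None and kept:
            rows.append((pid, death_age, DEAD, EXACT_DEATH,
                         gender01 or 0, education01 or 0))
    if n_dropped:
        logger.info("build_panel: %d non-classifiable waves skipped", n_dropped)
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    return panel


def prepare_panel(records: pd.DataFrame,
                  health_rule: str = "limitation",
                  hours_rule: str = "any") -> tuple[pd.DataFrame, dict]:
    """Filter eligibility then build the model-ready panel."""
    kept, log = filter_eligibility(records, health_rule, hours_rule)
    return build_panel(kept, health_rule, hours_rule), log


def cohort_of_panel(records: pd.DataFrame) -> pd.Series:
    """Per-person cohort labels of a raw-record frame."""
    return records.groupby("person_id")["birth_year"].first().map(assign_cohort)


def read_raw_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw record file lacks columns: {missing}")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file lacks columns: {missing}")
    return df


def panel_records(panel: pd.DataFrame) -> Iterable[PanelRecord]:
    for row in panel.itertuples(index=False):
        yield PanelRecord(row.person_id, float(row.age), int(row.state),
                          row.kind, int(row.gender01), int(row.education01))
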