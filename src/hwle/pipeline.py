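"""End-to-end analysis orchestration.

Runs, for each requested cohort and covariate specification: eligibility
filtering and panel construction, the multistate fit, the prevalence
fit, and the expectancies with simulation-based confidence intervals;
assembles the combined expectancy table (cohort x subgroup rows, the
five expectancy columns) and the sample-characteristics table; and
writes everything, plus a manifest with the configuration hash, into the
output directory.  Reruns with the same configuration and seed produce
identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expectancy import (ALL_KEYS, IntegrationSpec, STATE_KEYS,
                         simulate_confidence_intervals, temporary_expectancy)
from .model import COVARIATE_SETS, GompertzMultistateModel, ModelSpecification
from .prevalence import StatePrevalenceModel
from .states import (ALIVE_OBSERVATION, assign_cohort,
                     build_panel, filter_eligibility, read_raw_records)

logger = logging.getLogger(__name__)

COHORT_ORDER = ("HRS", "WB", "EBB")

#: subgroup label -> covariate values, per covariate set
SUBGROUPS = {
    "none": (("total", ()),),
    "gender": (("men", (0,)), ("women", (1,))),
    "education": (("low", (0,)), ("high", (1,))),
    "gender+education": (("men_low", (0, 0)), ("men_high", (0, 1)),
                         ("women_low", (1, 0)), ("women_high", (1, 1))),
}

#: long-format column order of the expectancy CSV
LONG_COLUMNS = ["cohort", "subgroup", "state", "estimate", "ci_low", "ci_high",
                "method", "age_start", "age_end", "n_draws", "seed"]

#: display name of each expectancy component
STATE_DISPLAY = {"healthy_working": "in_work_healthy",
                 "unhealthy_working": "in_work_unhealthy",
                 "wle": "in_work",
                 "not_working": "not_in_work",
                 "total": "life_expectancy"}


@dataclass
class AnalysisConfig:
    """Validated configuration of a full analysis run."""

    input_panel: str
    output_dir: str
    cohorts: tuple = COHORT_ORDER
    covariate_specs: tuple = ("none",)
    health_rule: str = "limitation"
    hours_rule: str = "any"
    age_window: tuple = (51.0, 80.0)
    integration_method: str = "step"
    step_h: float = 0.1
    grid_step: float = 0.5
    n_draws: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.cohorts:
            if c not in COHORT_ORDER:
                raise ValueError(f"unknown cohort {c!r}")
        for s in self.covariate_specs:
            if s not in COVARIATE_SETS:
                raise ValueError(f"unknown covariate spec {s!r}")
        if self.health_rule not in ("limitation", "self_rated"):
            raise ValueError(f"unknown health_rule {self.health_rule!r}")
        if self.hours_rule not in ("any", "min15"):
            raise ValueError(f"unknown hours_rule {self.hours_rule!r}")
        IntegrationSpec(self.integration_method, self.step_h, *self.age_window)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("cohorts", "covariate_specs", "age_window"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohorts"] = list(self.cohorts)
        d["covariate_specs"] = list(self.covariate_specs)
        d["age_window"] = list(self.age_window)
        return d

    def content_hash(self) -> str:
        # hash the analytical settings, not the storage locations
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("input_panel", "output_dir")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (documented splitting scheme)."""
    return int(np.random.SeedSequence(
        [int(base_seed), zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2 ** 31))


def summarize_sample(panels: dict) -> pd.DataFrame:
    """Sample-characteristics table: one row per cohort plus a total row.

    ``records`` counts survey responses (living observations);
    person-years are each person's last-minus-first observation age
    (death records included in the span).
    """
    rows = []
    for cohort, panel in panels.items():
        if len(panel) == 0:
            rows.append((cohort, 0, 0, 0.0, 0.0))
            continue
        n_ind = panel["person_id"].nunique()
        n_rec = int((panel["kind"] == ALIVE_OBSERVATION).sum())
        span = panel.groupby("person_id")["age"].agg(lambda a: a.max() - a.min())
        rows.append((cohort, n_ind, n_rec, n_rec / n_ind if n_ind else 0.0,
                     float(span.sum())))
    df = pd.DataFrame(rows, columns=[
        "cohort", "individuals", "records", "avg_records", "person_years"])
    tot_ind = df["individuals"].sum()
    tot_rec = df["records"].sum()
    total = pd.DataFrame([{
        "cohort": "Total", "individuals": tot_ind, "records": tot_rec,
        "avg_records": tot_rec / tot_ind if tot_ind else 0.0,
        "person_years": df["person_years"].sum()}])
    return pd.concat([df, total], ignore_index=True)


def expectancy_table(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long expectancy records into the report shape.

    Rows: cohort x subgroup; columns: the five expectancy components,
    each as estimate plus CI bounds.  The in-work column equals the sum
    of the two working columns by construction.
    """
    if len(long) == 0:
        return pd.DataFrame()
    out = []
    for (cohort, subgroup), g in long.groupby(["cohort", "subgroup"], sort=False):
        row = {"cohort": cohort, "subgroup": subgroup}
        for _, rec in g.iterrows():
            name = rec["state"]
            row[name] = rec["estimate"]
            row[f"{name}_lo"] = rec["ci_low"]
            row[f"{name}_hi"] = rec["ci_high"]
        out.append(row)
    return pd.DataFrame(out)


def _expectancies_for(fit, prev, config: AnalysisConfig, cohort: str,
                      spec_name: str) -> list[dict]:
    ispec = IntegrationSpec(config.integration_method, config.step_h,
                            *config.age_window)
    rows = []
    for subgroup, z in SUBGROUPS[spec_name]:
        seed = derive_seed(config.seed, f"ci:{cohort}:{spec_name}:{subgroup}")
        if fit.cov_usable:
            es = simulate_confidence_intervals(
                fit, prev, ispec, z, "marginal", config.n_draws, seed)
        else:
            logger.warning("%s/%s: covariance unusable, CIs disabled",
                           cohort, spec_name)
            es = temporary_expectancy(fit, prev, ispec, z, "marginal")
        for key in ("healthy_working", "unhealthy_working", "wle",
                    "not_working", "total"):
            rows.append({
                "cohort": cohort, "subgroup": subgroup,
                "state": STATE_DISPLAY[key],
                "estimate": es.estimates[key],
                "ci_low": es.ci_lower[key] if es.ci_lower else np.nan,
                "ci_high": es.ci_upper[key] if es.ci_upper else np.nan,
                "method": config.integration_method,
                "age_start": config.age_window[0],
                "age_end": config.age_window[1],
                "n_draws": config.n_draws if fit.cov_usable else 0,
                "seed": seed})
    return rows


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the result bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hwle")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: AnalysisConfig, outdir: Path) -> dict:
    raw = read_raw_records(config.input_panel)
    cohort_of = raw.groupby("person_id")["birth_year"].first().map(assign_cohort)

    panels, exclusions = {}, {}
    for cohort in config.cohorts:
        persons = cohort_of[cohort_of == cohort].index
        sub = raw[raw["person_id"].isin(persons)]
        if len(sub) == 0:
            panels[cohort] = pd.DataFrame(
                columns=["person_id", "age", "state", "kind",
                         "gender01", "education01"])
            exclusions[cohort] = {"input_persons": 0}
            continue
        kept, log = filter_eligibility(sub, config.health_rule,
                                       config.hours_rule)
        panels[cohort] = build_panel(kept, config.health_rule,
                                     config.hours_rule)
        exclusions[cohort] = log
        logger.info("cohort %s: exclusions %s", cohort, log)

    table1 = summarize_sample(panels)

    long_rows: list[dict] = []
    fits: dict = {}
    failures: dict = {}
    for cohort in config.cohorts:
        panel = panels[cohort]
        for spec_name in config.covariate_specs:
            key = f"{cohort}:{spec_name}"
            try:
                if len(panel) == 0:
                    raise ValueError("empty panel after filtering")
                mspec = ModelSpecification(spec_name,
                                           grid_step=config.grid_step)
                model = GompertzMultistateModel(panel, mspec)
                fit = model.fit()
                logger.info("%s: loglik %.2f converged=%s",
                            key, fit.llf, fit.converged)
                prev = StatePrevalenceModel(
                    panel, mspec.covariate_columns,
                    centering_age=config.age_window[0]).fit()
                fits[key] = (fit, prev)
                long_rows += _expectancies_for(fit, prev, config, cohort,
                                               spec_name)
            except Exception as err:  # keep partial results
                logger.error("%s failed: %s", key, err)
                failures[key] = str(err)
                for subgroup, _ in SUBGROUPS[spec_name]:
                    for key2 in ("healthy_working", "unhealthy_working",
                                 "wle", "not_working", "total"):
                        long_rows.append({
                            "cohort": cohort, "subgroup": subgroup,
                            "state": STATE_DISPLAY[key2], "estimate": np.nan,
                            "ci_low": np.nan, "ci_high": np.nan,
                            "method": config.integration_method,
                            "age_start": config.age_window[0],
                            "age_end": config.age_window[1],
                            "n_draws": 0, "seed": -1})

    long = pd.DataFrame(long_rows, columns=LONG_COLUMNS)
    table2 = expectancy_table(long)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {"hwle": __version__,
                     "numpy": np.__version__,
                     "pandas": pd.__version__,
                     "python": sys.version.split()[0]},
        "failures": failures,
        "exclusions": exclusions,
    }

    table1.to_csv(outdir / "table1_sample.csv", index=False)
    long.to_csv(outdir / "expectancies.csv", index=False)
    table2.to_csv(outdir / "table2_expectancies.csv", index=False)
    fitdir = outdir / "fits"
    fitdir.mkdir(exist_ok=True)
    for key, (fit, prev) in fits.items():
        stem = key.replace(":", "_").replace("+", "-")
        fit.save(fitdir / f"{stem}.msm.json")
        with open(fitdir / f"{stem}.prevalence.json", "w") as fh:
            json.dump(prev.to_dict(), fh, indent=1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {"table1": table1, "expectancies": long, "table2": table2,
            "fits": fits, "manifest": manifest, "exclusions": exclusions,
            "failures": failures}
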