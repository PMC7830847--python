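"""End-to-end pipeline: generate/load data, build the cohort, compute the
indicators, run the consensus round, the validity filter and the
reliability analysis, and emit the report tables.

The stage ledger tracks the indicator set through the pipeline:
candidates enter the scored survey round, survivors (plus the indicator
added by the panel) are audited for feasibility, feasible indicators are
checked against chart review, and the final set is profiled for
reliability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from lungqi.cohort import build_cohort, derive_covariates
from lungqi.delphi import response_rate, run_round, summarize_scores
from lungqi.errors import StageError
from lungqi.indicators.engine import EventIndex, clinimetrics, evaluate_all, patient_level
from lungqi.reliability import indicator_reliability
from lungqi.resources import load_catalog, load_delphi_defaults, load_milan_defaults
from lungqi.synth import CohortSpec, generate, simulate_chart_review, simulate_delphi_responses
from lungqi.validity import apply_validity_filter, discordance_table, stratified_sample

log = logging.getLogger("lungqi")


@dataclasses.dataclass
class PipelineConfig:
    """Everything one pipeline run needs; thresholds are percentages."""

    spec: Optional[CohortSpec] = None
    tables: Optional[dict] = None          # pre-loaded tables instead of generation
    sample_size: int = 114
    validity_threshold_pct: float = 20.0
    reliability_cutoff_pct: float = 70.0
    censor_date: str = "2016-12-31"
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.spec is None and self.tables is None:
            self.spec = CohortSpec(seed=self.seed)


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive cohort table: counts and percentages by key covariates."""
    n = len(cohort)
    blocks = []
    year = pd.to_datetime(cohort["incidence_date"]).dt.year
    for name, series in (
        ("year", year),
        ("sex", cohort["sex"]),
        ("age_class", cohort["age_class"]),
        ("charlson", cohort["charlson_class4"]),
        ("stage", cohort["stage_group"].where(cohort["stage_group"].notna(), "missing")),
        ("confirmed", cohort["confirmed"].map({True: "yes", False: "no"})),
        ("histology", cohort["histology"]),
        ("treatment", cohort["first_therapy"]),
    ):
        counts = series.value_counts().sort_index()
        for level, c in counts.items():
            blocks.append({"variable": name, "level": str(level), "n": int(c),
                           "pct": round(100.0 * c / n, 1)})
    return pd.DataFrame(blocks)


def indicator_table(results) -> pd.DataFrame:
    """Long-format indicator output: overall and per-stratum rows."""
    rows = []
    for res in results:
        if not res.feasible:
            rows.append({"indicator": res.id, "stratum": "overall", "level": "",
                         "numerator": np.nan, "denominator": np.nan, "pct": np.nan,
                         "note": f"infeasible: {res.reason}"})
            continue
        rows.append({"indicator": res.id, "stratum": "overall", "level": "",
                     "numerator": res.numerator, "denominator": res.denominator,
                     "pct": round(res.proportion, 1) if res.denominator else np.nan, "note": ""})
        for stratum, cells in res.strata.items():
            for level, (k, m) in sorted(cells.items(), key=lambda kv: str(kv[0])):
                rows.append({"indicator": res.id, "stratum": stratum, "level": str(level),
                             "numerator": k, "denominator": m,
                             "pct": round(100.0 * k / m, 1) if m else np.nan, "note": ""})
    return pd.DataFrame(rows)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, str(exc)) from exc
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: Optional[PipelineConfig] = None) -> dict:
    """Run every stage and return the report bundle.

    The bundle carries the cohort summary, the indicator table, the
    chart-review discordance table, the reliability table and the stage
    ledger; with ``config.out_dir`` set, everything is also written as
    CSV + JSON.  Stage failures raise :class:`~lungqi.errors.StageError`
    naming the stage; previously completed outputs stay in the bundle the
    caller can inspect.
    """
    config = config or PipelineConfig()
    catalog = load_catalog()
    bundle: dict = {"config": {"seed": config.seed, "sample_size": config.sample_size}}

    # ---- stage 1: data ---------------------------------------------------
    @_stage("synthgen")
    def stage_data():
        if config.tables is not None:
            for required in ("registry", "inpatient", "outpatient", "prescriptions", "emergency"):
                if required not in config.tables:
                    raise FileNotFoundError(f"input not found: {required}")
            return config.tables
        return generate(config.spec).tables

    tables = stage_data()
    events = {k: v for k, v in tables.items() if k != "registry"}

    # ---- stage 2: cohort -------------------------------------------------
    @_stage("cohort_builder")
    def stage_cohort():
        retained, exclusions = build_cohort(tables["registry"])
        cov = derive_covariates(retained, events)
        return cov, exclusions

    cohort, exclusions = stage_cohort()
    bundle["exclusions"] = exclusions
    bundle["cohort_summary"] = cohort_summary(cohort)

    # ---- stage 3: delphi round -------------------------------------------
    @_stage("delphi")
    def stage_delphi():
        cfg = load_delphi_defaults()
        responses = simulate_delphi_responses(cfg, seed=config.seed)
        outcome = run_round(responses)
        retained = sorted(outcome.loc[outcome["status"] == "retained", "indicator_id"])
        panel_added = [d.id for d in catalog if d.panel_added]
        return {
            "responses": responses,
            "outcome": outcome,
            "scores": summarize_scores(responses),
            "retained_round1": retained,
            "panel_added": panel_added,
            "response_rate_pct": response_rate(cfg["invited"], cfg["responded"]),
            "n_candidates": len(outcome),
        }

    delphi = stage_delphi()
    bundle["delphi"] = {k: delphi[k] for k in ("outcome", "scores", "retained_round1",
                                               "panel_added", "response_rate_pct", "n_candidates")}
    selected = sorted(set(delphi["retained_round1"]) | set(delphi["panel_added"]))

    # ---- stage 4: indicators + feasibility -------------------------------
    @_stage("indicator_engine")
    def stage_indicators():
        results = evaluate_all(cohort, events, catalog, config.censor_date)
        return results

    results = stage_indicators()
    bundle["indicator_table"] = indicator_table(results)
    infeasible = sorted({r.id for r in results if not r.feasible})
    feasible_base = [b for b in catalog.base_ids if b in selected and b not in infeasible]

    # ---- stage 5: criterion validity -------------------------------------
    @_stage("criterion_validity")
    def stage_validity():
        sample = stratified_sample(cohort, config.sample_size, seed=config.seed)
        sample_ids = set(sample["patient_id"])
        chart = {k: v for k, v in load_milan_defaults()["chart_review"].items()
                 if isinstance(v, list)}
        rates = {ind: d / n for ind, (d, n) in chart.items() if ind in feasible_base}
        db_values = {
            ind: patient_level(catalog[ind], cohort, events, config.censor_date, catalog)
            for ind in rates
        }
        records = simulate_chart_review(db_values, miss_rates=rates, sample=sample_ids,
                                        seed=config.seed)
        table = discordance_table(records)
        unevaluated = [b for b in feasible_base if b not in rates]
        retained, eliminated = apply_validity_filter(
            table, config.validity_threshold_pct, unevaluated=unevaluated
        )
        return sample, records, table, retained, eliminated

    sample, records, disc_table, valid_retained, valid_eliminated = stage_validity()
    bundle["discordance_table"] = disc_table
    bundle["validity"] = {"retained": valid_retained, "eliminated": valid_eliminated,
                          "sample_size": len(sample)}
    final_set = [b for b in feasible_base if b not in valid_eliminated]

    # ---- stage 6: reliability + clinimetrics ------------------------------
    @_stage("reliability")
    def stage_reliability():
        rows = []
        for base in final_set:
            defs = [d for d in catalog if d.base_id == base]
            for d in defs:
                res = next(r for r in results if r.id == d.id)
                if not res.defined:
                    continue
                outcomes = patient_level(d, cohort, events, config.censor_date, catalog)
                rel = indicator_reliability(outcomes, cutoff_pct=config.reliability_cutoff_pct)
                clin = clinimetrics(res)
                rows.append(
                    {
                        "indicator": d.id,
                        "n_patients": res.denominator,
                        "n_providers": clin["n_providers"],
                        "floor": clin["floor"],
                        "ceiling": clin["ceiling"],
                        "tau2": round(rel["fit"]["tau2"], 4),
                        "n_reliable": rel["summary"]["n_reliable"],
                        "pct_reliable": round(rel["summary"]["pct_reliable"], 1),
                        "mean": round(clin["mean"], 1),
                        "sd": round(clin["sd"], 1),
                        "median": round(clin["median"], 1),
                        "q1": round(clin["q1"], 1),
                        "q3": round(clin["q3"], 1),
                    }
                )
        return pd.DataFrame(rows)

    bundle["reliability_table"] = stage_reliability()

    # ---- ledger -----------------------------------------------------------
    n_cand = delphi["n_candidates"]
    bundle["ledger"] = {
        "candidates": n_cand,
        "excluded_round1": n_cand - len(delphi["retained_round1"]),
        "after_round1": len(delphi["retained_round1"]),
        "panel_added": delphi["panel_added"],
        "selected": len(selected),
        "infeasible": infeasible,
        "feasible": len(feasible_base),
        "eliminated_validity": valid_eliminated,
        "final": len(final_set),
        "final_set": final_set,
    }

    if config.out_dir:
        _write_bundle(bundle, config.out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("cohort_summary", "indicator_table", "discordance_table", "reliability_table"):
        if key in bundle and isinstance(bundle[key], pd.DataFrame):
            bundle[key].to_csv(out / f"{key}.csv", index=False)
    machine = {
        "exclusions": bundle.get("exclusions"),
        "ledger": bundle.get("ledger"),
        "validity": bundle.get("validity"),
        "delphi_response_rate_pct": bundle.get("delphi", {}).get("response_rate_pct"),
        "config": bundle.get("config"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(machine, fh, indent=2, default=str)
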