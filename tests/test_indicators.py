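"""Indicator engine: brute-force oracle equivalence, window semantics,
feasibility auditing and provider clinimetrics."""

import numpy as np
import pandas as pd
import pytest

from lungqi.errors import ConfigurationError
from lungqi.indicators.engine import check_feasibility, clinimetrics, evaluate, evaluate_all
from lungqi.indicators.model import IndicatorDefinition

from conftest import CENSOR, cohort_from_tables, make_tables
from oracles import FEASIBLE_IDS, oracle_counts

EVENT_CODES = [
    ("outpatient", "CT_THORAX"), ("outpatient", "PET"), ("outpatient", "CT_HEAD"),
    ("outpatient", "BONE_SCAN"), ("outpatient", "CT_ABDOMEN"), ("outpatient", "MR_HEAD"),
    ("outpatient", "US_ABDOMEN"), ("outpatient", "BRONCHOSCOPY"), ("outpatient", "NEEDLE_BIOPSY"),
    ("outpatient", "CHEMO"), ("outpatient", "RT_FRACTION"), ("outpatient", "GP_VISIT"),
    ("outpatient", "FOLLOWUP_VISIT"), ("prescriptions", "OPIOID_ATC"),
    ("emergency", "EMERGENCY_ACCESS"),
]
SURGERY_CODES = ["WEDGE_RESECTION", "SEGMENTECTOMY", "LOBECTOMY", "PNEUMONECTOMY"]
# offsets deliberately hit the window boundaries (+-30/45/60/90 days)
OFFSETS = [-200, -95, -91, -90, -89, -61, -60, -46, -45, -44, -31, -30, -29, -15,
           -5, -1, 0, 1, 15, 29, 30, 31, 45, 60, 61, 90, 120, 180, 400, 760, 1100]


def random_fixture(seed: int, n: int = 18) -> dict:
    """A small random cohort whose events straddle every indicator window."""
    rng = np.random.default_rng(seed)
    base = pd.Timestamp("2010-03-01")
    patients, events = [], []
    stages = ["I", "IIA", "IIB", "IIIA", "IIIB", "IV", None]
    for i in range(n):
        pid = f"T{i:03d}"
        confirmed = bool(rng.random() < 0.8)
        morph = int(rng.choice([8041, 8070, 8140])) if confirmed else None
        inc = base + pd.Timedelta(days=int(rng.integers(0, 600)))
        death = None
        if rng.random() < 0.6:
            death = inc + pd.Timedelta(days=int(rng.integers(0, 2600)))
        patients.append(
            {
                "patient_id": pid,
                "incidence_date": str(inc.date()),
                "morphology": morph if morph is not None else np.nan,
                "confirmed": confirmed,
                "stage": rng.choice(stages),
                "death_date": str(death.date()) if death is not None else None,
            }
        )
        for _ in range(int(rng.integers(0, 10))):
            table, code = EVENT_CODES[int(rng.integers(0, len(EVENT_CODES)))]
            offset = int(rng.choice(OFFSETS))
            events.append(
                {
                    "patient_id": pid,
                    "table": table,
                    "date": str((inc + pd.Timedelta(days=offset)).date()),
                    "code": code,
                    "provider_id": f"P{int(rng.integers(1, 6)):03d}",
                }
            )
        for _ in range(int(rng.integers(0, 3))):
            code = str(rng.choice(SURGERY_CODES))
            start = inc + pd.Timedelta(days=int(rng.choice([0, 10, 30, 40, 100, 200])))
            events.append(
                {
                    "patient_id": pid,
                    "table": "inpatient",
                    "date": str(start.date()),
                    "code": code,
                    "discharge_date": str((start + pd.Timedelta(days=int(rng.choice([5, 14, 15, 21])))).date()),
                    "provider_id": f"P{int(rng.integers(1, 6)):03d}",
                }
            )
    return make_tables(patients, events)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_engine_matches_bruteforce_oracle(seed, catalog):
    """Every feasible indicator rule agrees with an independent per-patient
    transcription of its clinical description on random small cohorts."""
    tables = random_fixture(seed)
    cohort, events = cohort_from_tables(tables)
    for ind in FEASIBLE_IDS:
        res = evaluate(catalog[ind], cohort, events, CENSOR, catalog, with_providers=False)
        num, den = oracle_counts(tables, ind, CENSOR)
        assert (res.numerator, res.denominator) == (num, den), ind


def test_second_surgery_fixture(catalog):
    """One of six surgical patients re-operated at day 20 fails the
    no-second-surgery rule."""
    patients = [{"patient_id": f"S{i}", "stage": "I"} for i in range(6)]
    events = []
    for i in range(6):
        events.append({"patient_id": f"S{i}", "table": "inpatient", "date": "2010-07-01",
                       "code": "LOBECTOMY", "discharge_date": "2010-07-08"})
    events.append({"patient_id": "S0", "table": "inpatient", "date": "2010-07-21",
                   "code": "WEDGE_RESECTION", "discharge_date": "2010-07-25"})
    tables = make_tables(patients, events)
    cohort, ev = cohort_from_tables(tables)
    res = evaluate(catalog["S6"], cohort, ev, CENSOR, catalog)
    assert (res.numerator, res.denominator) == (5, 6)
    assert oracle_counts(tables, "S6") == (5, 6)


def test_window_boundaries_inclusive(catalog):
    """An event exactly on a window boundary counts (both endpoints)."""
    for offset, expected in ((-45, 1), (-46, 0), (-1, 1)):
        tables = make_tables(
            [{"patient_id": "A", "stage": "I"}],
            [
                {"patient_id": "A", "table": "inpatient", "date": "2010-09-01",
                 "code": "LOBECTOMY", "discharge_date": "2010-09-08"},
                {"patient_id": "A", "table": "outpatient", "code": "PET",
                 "date": str((pd.Timestamp("2010-09-01") + pd.Timedelta(days=offset)).date())},
            ],
        )
        cohort, ev = cohort_from_tables(tables)
        res = evaluate(catalog["O2"], cohort, ev, CENSOR, catalog)
        assert res.numerator == expected, offset


def test_adding_numerator_event_is_monotone(catalog, milan_spec):
    """Adding a qualifying numerator event never decreases the proportion."""
    tables = random_fixture(11)
    cohort, ev = cohort_from_tables(tables)
    before = evaluate(catalog["D1"], cohort, ev, CENSOR, catalog)
    extra = pd.DataFrame(
        [{"patient_id": pid, "provider_id": "P001",
          "date": pd.Timestamp(inc) + pd.Timedelta(days=10), "code": "CT_THORAX"}
         for pid, inc in zip(cohort["patient_id"], cohort["incidence_date"])]
    )
    ev2 = dict(ev)
    ev2["outpatient"] = pd.concat([ev["outpatient"], extra], ignore_index=True)
    after = evaluate(catalog["D1"], cohort, ev2, CENSOR, catalog)
    assert after.denominator == before.denominator
    assert after.numerator >= before.numerator
    assert after.numerator == after.denominator


def test_stage_strata_partition(milan_results, milan_cohort):
    """Stage-stratum counts sum to the overall counts minus missing-stage
    patients; all-patient strata partition the full denominator."""
    for res in milan_results:
        if not res.feasible:
            continue
        stage_cells = res.strata["stage_group"].values()
        assert sum(c[1] for c in stage_cells) <= res.denominator
        sex_cells = res.strata["sex"].values()
        assert sum(c[1] for c in sex_cells) == res.denominator
        assert sum(c[0] for c in sex_cells) == res.numerator


def test_feasibility_threshold_boundary(catalog):
    """Code used by exactly the threshold fraction of providers is feasible;
    below it or absent is not."""
    defn = catalog["O3"]  # requires MDT_EVAL
    def usage(n_providers_using):
        return {
            "outpatient": pd.DataFrame(
                {
                    "patient_id": [f"X{i}" for i in range(n_providers_using)],
                    "provider_id": [f"P{i + 1:03d}" for i in range(n_providers_using)],
                    "date": pd.Timestamp("2010-01-01"),
                    "code": "MDT_EVAL",
                }
            )
        }
    ok, _ = check_feasibility(defn, usage(5), n_providers=100, min_provider_fraction=0.05)
    assert ok  # exactly 5% is inclusive
    bad, reason = check_feasibility(defn, usage(2), n_providers=100)
    assert not bad and "MDT_EVAL" in reason
    absent, reason = check_feasibility(defn, {"outpatient": pd.DataFrame(
        columns=["patient_id", "provider_id", "date", "code"])}, n_providers=100)
    assert not absent and "absent" in reason


def test_milan_feasibility_flags(milan_results):
    """The default cohort yields 19 computable indicators and three
    infeasibility notices for the never/rarely coded procedures."""
    infeasible = {r.id for r in milan_results if not r.feasible}
    assert infeasible == {"O3", "S3", "M3"}
    feasible_base = {r.id.split("y")[0] for r in milan_results if r.feasible}
    assert len(feasible_base) == 19


def test_empty_cohort_flagged_undefined(catalog):
    tables = make_tables([], [])
    cohort, ev = cohort_from_tables(tables)
    results = evaluate_all(cohort, ev, catalog, CENSOR, n_providers=10, force_infeasible=True)
    assert all(r.denominator == 0 and not r.defined for r in results)


def test_unknown_code_token_is_configuration_error(catalog):
    bad = IndicatorDefinition(
        id="ZZ", base_id="ZZ", section="test", short_name="bad",
        denominator={"all": True},
        numerator={"has_event": {"codes": ["NO_SUCH_CODE"]}},
    )
    tables = make_tables([{"patient_id": "A"}], [])
    cohort, ev = cohort_from_tables(tables)
    with pytest.raises(ConfigurationError):
        evaluate(bad, cohort, ev, CENSOR, catalog)


def test_clinimetrics_summaries():
    def result_with(ps):
        from lungqi.indicators.engine import IndicatorResult
        prov = pd.DataFrame({"provider_id": [f"P{i}" for i in range(len(ps))],
                             "n": [10] * len(ps), "k": [int(p / 10) for p in ps]})
        prov["p"] = ps
        return IndicatorResult(id="X", short_name="x", numerator=0, denominator=1, providers=prov)

    summary = clinimetrics(result_with([0.0, 50.0, 100.0, 100.0]))
    assert summary["floor"] == 1 and summary["ceiling"] == 2 and summary["median"] == 75.0
    single = clinimetrics(result_with([40.0]))
    assert single["median"] == single["q1"] == single["q3"] == 40.0
    allfull = clinimetrics(result_with([100.0, 100.0, 100.0]))
    assert allfull["ceiling"] == 3 and allfull["sd"] == 0.0
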