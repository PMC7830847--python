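import numpy as np
import pandas as pd
import pytest

from lungqi.cohort import build_cohort, derive_covariates
from lungqi.indicators.engine import evaluate_all
from lungqi.resources import load_catalog
from lungqi.synth import CohortSpec, complete_targets, generate

CENSOR = "2016-12-31"


def day(datestr: str) -> pd.Timestamp:
    return pd.Timestamp(datestr)


def make_tables(patients: list[dict], events: list[dict]) -> dict[str, pd.DataFrame]:
    """Build the five linked tables from compact per-test specifications.

    ``patients``: dicts with patient_id and optional registry fields.
    ``events``: dicts with patient_id, table, date, code and optional
    provider_id / discharge_date.
    """
    reg_rows = []
    for p in patients:
        reg_rows.append(
            {
                "patient_id": p["patient_id"],
                "sex": p.get("sex", "M"),
                "birth_date": day(p.get("birth_date", "1945-06-01")),
                "incidence_date": day(p.get("incidence_date", "2010-06-01")),
                "topography": p.get("topography", "C34.1"),
                "morphology": p.get("morphology", 8140),
                "confirmed": p.get("confirmed", True),
                "stage": p.get("stage"),
                "dco": p.get("dco", False),
                "death_date": day(p["death_date"]) if p.get("death_date") else pd.NaT,
            }
        )
    registry = pd.DataFrame(
        reg_rows,
        columns=["patient_id", "sex", "birth_date", "incidence_date", "topography",
                 "morphology", "confirmed", "stage", "dco", "death_date"],
    )
    tables = {"registry": registry}
    for name in ("inpatient", "outpatient", "prescriptions", "emergency"):
        rows = []
        for ev in events:
            if ev["table"] != name:
                continue
            row = {
                "patient_id": ev["patient_id"],
                "provider_id": ev.get("provider_id", "P001"),
                "date": day(ev["date"]),
                "code": ev["code"],
            }
            if name == "inpatient":
                row["discharge_date"] = day(ev["discharge_date"]) if ev.get("discharge_date") else pd.NaT
            rows.append(row)
        cols = ["patient_id", "provider_id", "date", "code"] + (
            ["discharge_date"] if name == "inpatient" else []
        )
        tables[name] = pd.DataFrame(rows, columns=cols)
    return tables


def cohort_from_tables(tables: dict) -> tuple[pd.DataFrame, dict]:
    retained, _ = build_cohort(tables["registry"])
    events = {k: v for k, v in tables.items() if k != "registry"}
    return derive_covariates(retained, events), events


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def milan_spec():
    return CohortSpec(seed=20260924)


@pytest.fixture(scope="session")
def milan_data(milan_spec):
    return generate(milan_spec)


@pytest.fixture(scope="session")
def milan_cohort(milan_data):
    retained, _ = build_cohort(milan_data.registry)
    return derive_covariates(retained, milan_data.events)


@pytest.fixture(scope="session")
def milan_results(milan_cohort, milan_data, catalog):
    return evaluate_all(milan_cohort, milan_data.events, catalog, CENSOR)


@pytest.fixture(scope="session")
def milan_targets(milan_spec):
    return complete_targets(milan_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
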