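"""Analysis-cohort construction from the registry and linked databases.

The registry provides the base population (ICD-O-3 topography C33-C34);
death-certificate-only and mesenchymal-histology cases are excluded, then
patient-level covariates are derived: histology group (SCLC vs NSCLC),
age classes, the registry-linkage Charlson comorbidity score over a
12-month pre-incidence lookback, and the type and date of first therapy.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from lungqi.errors import DuplicatePatientError
from lungqi.indicators.model import Event, stage_group, to_day, from_day
from lungqi.indicators.engine import EventIndex
from lungqi.resources import load_codes

SCLC_MORPHOLOGY = range(8041, 8046)
#: ICD-O-3 morphology block for mesenchymal (soft-tissue) tumours
MESENCHYMAL_MORPHOLOGY = range(8800, 9000)

#: descriptive age classes of the cohort summary
AGE_CLASS_EDGES = [(0, 55, "<=55"), (56, 60, "56-60"), (61, 65, "61-65"),
                   (66, 70, "66-70"), (71, 75, "71-75"), (76, 80, "76-80"),
                   (81, 200, ">80")]
#: age strata for stratified indicator output
AGE_STRATUM_EDGES = [(0, 60, "<=60"), (61, 70, "61-70"), (71, 200, ">=71")]

FIRST_THERAPY_ASCERTAINMENT_DAYS = 180
CHEMORADIATION_GAP_DAYS = 90
CHARLSON_LOOKBACK_DAYS = 365


def is_mesenchymal(morphology) -> bool:
    if morphology is None or (isinstance(morphology, float) and np.isnan(morphology)):
        return False
    return int(morphology) in MESENCHYMAL_MORPHOLOGY


def classify_histology(morphology, confirmed: bool = True) -> str:
    """SCLC for confirmed morphology 8041-8045; NSCLC in every other case.

    Nonspecific morphologies and cyto-histologically unconfirmed cases are
    grouped with NSCLC, whose guidelines apply by default.
    """
    if morphology is None or (isinstance(morphology, float) and np.isnan(morphology)):
        return "NSCLC"
    if not confirmed:
        return "NSCLC"
    return "SCLC" if int(morphology) in SCLC_MORPHOLOGY else "NSCLC"


def build_cohort(registry: pd.DataFrame):
    """Apply the cohort exclusions and return (retained, exclusion_log).

    Excludes death-certificate-only cases and mesenchymal histologies; the
    log counts every reason.  Raises on duplicate patient IDs.
    """
    dup = registry["patient_id"][registry["patient_id"].duplicated()]
    if len(dup):
        raise DuplicatePatientError(sorted(dup.unique()))
    dco_mask = registry["dco"].astype(bool)
    mes_mask = ~dco_mask & registry["morphology"].map(is_mesenchymal)
    retained = registry[~dco_mask & ~mes_mask].reset_index(drop=True)
    log = {
        "input": int(len(registry)),
        "excluded_dco": int(dco_mask.sum()),
        "excluded_mesenchymal": int(mes_mask.sum()),
        "retained": int(len(retained)),
    }
    return retained, log


def _class_of(age: int, edges) -> str:
    for lo, hi, label in edges:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside class edges")


def charlson_index(
    incidence_date,
    events: Iterable[Event],
    charlson_map: Optional[dict] = None,
    lookback_days: int = CHARLSON_LOOKBACK_DAYS,
):
    """Registry-linkage Charlson score over the pre-incidence lookback.

    Sums the standard condition weights over *distinct* conditions coded in
    the inpatient or outpatient databases in the ``lookback_days`` before
    incidence (the index cancer and other malignancy categories are not in
    the condition dictionary, so they never contribute).  Returns
    ``(score, cls3, cls4)`` with the 3-level class used for stratification
    ('0', '1-2', '>=3') and the 4-level descriptive class
    ('0', '1', '2', '>=3').
    """
    if charlson_map is None:
        charlson_map = load_codes()["charlson"]
    inc = to_day(incidence_date)
    seen = {}
    for ev in events:
        meta = charlson_map.get(ev.code)
        if meta is None or ev.table not in ("inpatient", "outpatient"):
            continue
        if inc - lookback_days <= ev.day <= inc - 1:
            seen[meta["condition"]] = meta["weight"]
    score = int(sum(seen.values()))
    cls3 = "0" if score == 0 else ("1-2" if score <= 2 else ">=3")
    cls4 = str(score) if score <= 2 else ">=3"
    return score, cls3, cls4


def assign_first_therapy(
    incidence_date,
    events: Iterable[Event],
    ascertainment_days: int = FIRST_THERAPY_ASCERTAINMENT_DAYS,
    chemoradiation_gap: int = CHEMORADIATION_GAP_DAYS,
    code_groups: Optional[dict] = None,
):
    """First therapy type and date.

    The first therapy is the earliest surgery/chemotherapy/radiotherapy
    event on or after incidence within the ascertainment window.  When the
    earliest modality is medical and chemotherapy and radiotherapy each
    start within ``chemoradiation_gap`` days of the other, the first
    therapy is classified as chemo-radiation (dated at the earlier of the
    two starts).  Returns ``('none', None)`` when no treatment is found.
    """
    if code_groups is None:
        code_groups = load_codes()["groups"]
    surgery = set(code_groups["lung_surgery"])
    chemo = set(code_groups["chemo"])
    rt = set(code_groups["radiotherapy"])
    inc = to_day(incidence_date)
    lo, hi = inc, inc + ascertainment_days

    first = {}
    for ev in sorted(events, key=lambda e: e.day):
        if ev.day < inc:
            continue
        if ev.code in surgery and "surgery" not in first:
            first["surgery"] = ev.day
        elif ev.code in chemo and "chemotherapy" not in first:
            first["chemotherapy"] = ev.day
        elif ev.code in rt and "radiotherapy" not in first:
            first["radiotherapy"] = ev.day
    in_window = {k: d for k, d in first.items() if lo <= d <= hi}
    if not in_window:
        return "none", None
    kind, day = min(in_window.items(), key=lambda kv: (kv[1], kv[0]))
    if kind == "surgery":
        return "surgery", from_day(day)
    c, r = first.get("chemotherapy"), first.get("radiotherapy")
    if c is not None and r is not None and abs(c - r) <= chemoradiation_gap:
        return "chemoradiation", from_day(min(c, r))
    return kind, from_day(day)


def derive_covariates(
    cohort: pd.DataFrame,
    events: dict[str, pd.DataFrame] | EventIndex,
    ascertainment_days: int = FIRST_THERAPY_ASCERTAINMENT_DAYS,
) -> pd.DataFrame:
    """Attach all derived patient-level covariates to a built cohort.

    Adds: ``age``, ``age_class``, ``age_stratum``, ``stage_group``,
    ``histology``, ``charlson_score``, ``charlson_class`` (3-level),
    ``charlson_class4``, ``first_therapy`` and ``first_therapy_date``.
    """
    codes = load_codes()
    index = events if isinstance(events, EventIndex) else EventIndex(events)
    out = cohort.copy()

    inc = pd.to_datetime(out["incidence_date"])
    birth = pd.to_datetime(out["birth_date"])
    age = ((inc - birth).dt.days / 365.25).astype(int)
    out["age"] = age
    out["age_class"] = [_class_of(a, AGE_CLASS_EDGES) for a in age]
    out["age_stratum"] = [_class_of(a, AGE_STRATUM_EDGES) for a in age]
    out["stage_group"] = [stage_group(None if pd.isna(s) else s) for s in out["stage"]]
    out["histology"] = [
        classify_histology(m, bool(c)) for m, c in zip(out["morphology"], out["confirmed"])
    ]

    scores, cls3s, cls4s, ft_types, ft_dates = [], [], [], [], []
    for pid, inc_date in zip(out["patient_id"], out["incidence_date"]):
        evs = index.events_for(pid)
        score, cls3, cls4 = charlson_index(inc_date, evs, codes["charlson"])
        ft_type, ft_date = assign_first_therapy(
            inc_date, evs, ascertainment_days, code_groups=codes["groups"]
        )
        scores.append(score)
        cls3s.append(cls3)
        cls4s.append(cls4)
        ft_types.append(ft_type)
        ft_dates.append(ft_date)
    out["charlson_score"] = scores
    out["charlson_class"] = cls3s
    out["charlson_class4"] = cls4s
    out["first_therapy"] = ft_types
    out["first_therapy_date"] = ft_dates
    return out
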