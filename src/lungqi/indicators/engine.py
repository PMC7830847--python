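"""Indicator evaluation over a cohort and its linked event tables.

Produces, for each indicator, exact numerator/denominator counts overall,
within strata (age class, sex, Charlson class, stage I-IV) and per
attributed provider, plus provider-level clinimetric summaries (median,
quartiles, floor/ceiling counts).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd

from lungqi.errors import ConfigurationError
from lungqi.indicators.model import (
    EVENT_TABLES,
    Event,
    IndicatorCatalog,
    IndicatorDefinition,
    PatientCtx,
    to_day,
)

#: strata reported alongside the overall proportion
STRATA = ("age_stratum", "sex", "charlson_class", "stage_group")
#: stage strata drop missing-stage patients; other strata cover everyone
STAGE_LEVELS = ("I", "II", "III", "IV")


@dataclasses.dataclass
class IndicatorResult:
    """Counts for one indicator: overall, per stratum and per provider."""

    id: str
    short_name: str
    numerator: int
    denominator: int
    feasible: bool = True
    reason: Optional[str] = None
    year: Optional[int] = None
    strata: dict = dataclasses.field(default_factory=dict)
    providers: Optional[pd.DataFrame] = None  # columns: provider_id, n, k, p

    @property
    def proportion(self) -> float:
        """Indicator value in percent; NaN when the denominator is empty."""
        if self.denominator == 0:
            return float("nan")
        return 100.0 * self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.feasible and self.denominator > 0


class EventIndex:
    """Per-patient sorted event lists built once from the five raw tables."""

    def __init__(self, events: dict[str, pd.DataFrame]):
        self._by_patient: dict[str, list[Event]] = {}
        rows = []
        for table in EVENT_TABLES:
            df = events.get(table)
            if df is None or len(df) == 0:
                continue
            has_discharge = "discharge_date" in df.columns
            day = pd.to_datetime(df["date"]).values.astype("datetime64[D]").astype(int)
            dis = (
                pd.to_datetime(df["discharge_date"]).values.astype("datetime64[D]").astype("float64")
                if has_discharge
                else np.full(len(df), np.nan)
            )
            for pid, prov, code, d, dd in zip(
                df["patient_id"].to_numpy(),
                df["provider_id"].to_numpy(),
                df["code"].to_numpy(),
                day,
                dis,
            ):
                rows.append((pid, int(d), str(code), table, str(prov), None if math.isnan(dd) else int(dd)))
        rows.sort(key=lambda r: (r[0], r[1], r[3], r[2]))
        for pid, d, code, table, prov, dd in rows:
            self._by_patient.setdefault(pid, []).append(Event(d, code, table, prov, dd))

    def events_for(self, patient_id: str) -> list[Event]:
        return self._by_patient.get(patient_id, [])

    def patients(self):
        return self._by_patient.keys()


def _contexts(cohort: pd.DataFrame, index: EventIndex, censor: int, code_groups: dict):
    for row in cohort.itertuples(index=False):
        yield PatientCtx(row, index.events_for(row.patient_id), censor, code_groups)


def _attributed_provider(defn: IndicatorDefinition, ctx: PatientCtx, evaluator) -> Optional[str]:
    """Provider of the earliest relevant procedure (ties: smallest provider ID)."""
    kind = defn.attribution.get("kind", "any_contact")
    if kind == "any_contact":
        candidates = ctx.events
    elif kind == "event":
        codes = evaluator.resolve_codes(defn.attribution["codes"])
        candidates = [ev for ev in ctx.events if ev.code in codes]
    elif kind == "first_therapy":
        codes = (
            evaluator.resolve_codes("lung_surgery")
            | evaluator.resolve_codes("chemo")
            | evaluator.resolve_codes("radiotherapy")
        )
        candidates = [ev for ev in ctx.events if ev.code in codes]
    else:  # pragma: no cover - guarded by catalog validation
        raise ConfigurationError(f"unknown attribution kind {kind!r}")
    if not candidates:
        return None
    first_day = min(ev.day for ev in candidates)
    return min(ev.provider for ev in candidates if ev.day == first_day)


def evaluate(
    defn: IndicatorDefinition,
    cohort: pd.DataFrame,
    events: dict[str, pd.DataFrame] | EventIndex,
    censor_date,
    catalog: IndicatorCatalog,
    with_providers: bool = True,
) -> IndicatorResult:
    """Compute one indicator exactly over the cohort.

    ``cohort`` must carry the derived covariates (histology, stage,
    first therapy, Charlson class); see :func:`lungqi.cohort.derive_covariates`.
    """
    index = events if isinstance(events, EventIndex) else EventIndex(events)
    censor = to_day(censor_date)
    evaluator = catalog.evaluator
    groups = evaluator.code_groups

    num = den = 0
    strata: dict = {name: {} for name in STRATA}
    prov_n: dict[str, int] = {}
    prov_k: dict[str, int] = {}

    for ctx in _contexts(cohort, index, censor, groups):
        if not evaluator.evaluate(defn.denominator, ctx):
            continue
        den += 1
        success = evaluator.evaluate(defn.numerator, ctx)
        if success:
            num += 1
        row = ctx.row
        for name in STRATA:
            level = getattr(row, name)
            if name == "stage_group" and (level is None or (isinstance(level, float) and np.isnan(level))):
                continue  # stage strata drop missing-stage patients
            cell = strata[name].setdefault(level, [0, 0])
            cell[1] += 1
            cell[0] += int(success)
        if with_providers:
            prov = _attributed_provider(defn, ctx, evaluator)
            if prov is not None:
                prov_n[prov] = prov_n.get(prov, 0) + 1
                prov_k[prov] = prov_k.get(prov, 0) + int(success)

    providers = None
    if with_providers:
        providers = pd.DataFrame(
            {
                "provider_id": sorted(prov_n),
                "n": [prov_n[p] for p in sorted(prov_n)],
                "k": [prov_k[p] for p in sorted(prov_n)],
            }
        )
        providers["p"] = np.where(providers["n"] > 0, 100.0 * providers["k"] / providers["n"], np.nan)

    return IndicatorResult(
        id=defn.id,
        short_name=defn.short_name,
        numerator=num,
        denominator=den,
        year=defn.year,
        strata={name: {lvl: tuple(c) for lvl, c in cells.items()} for name, cells in strata.items()},
        providers=providers,
    )


def check_feasibility(
    defn: IndicatorDefinition,
    events: dict[str, pd.DataFrame],
    n_providers: int,
    min_provider_fraction: float = 0.05,
):
    """Audit whether the codes an indicator needs are actually in use.

    An indicator is infeasible when any required code token is absent from
    the databases or used by fewer than ``min_provider_fraction`` of
    providers (boundary inclusive: exactly the threshold is feasible).
    Returns ``(True, None)`` or ``(False, reason)``.
    """
    if not defn.required_codes:
        return True, None
    usage: dict[str, set] = {tok: set() for tok in defn.required_codes}
    for table in EVENT_TABLES:
        df = events.get(table)
        if df is None or len(df) == 0:
            continue
        for tok in defn.required_codes:
            mask = df["code"] == tok
            if mask.any():
                usage[tok].update(df.loc[mask, "provider_id"].unique())
    for tok, provs in usage.items():
        if not provs:
            return False, f"code {tok} absent from the databases"
        frac = len(provs) / n_providers
        if frac < min_provider_fraction:
            return False, (
                f"code {tok} used by only {len(provs)} of {n_providers} providers "
                f"({100 * frac:.1f}% < {100 * min_provider_fraction:.0f}%)"
            )
    return True, None


def evaluate_all(
    cohort: pd.DataFrame,
    events: dict[str, pd.DataFrame],
    catalog: IndicatorCatalog,
    censor_date,
    n_providers: Optional[int] = None,
    min_provider_fraction: float = 0.05,
    force_infeasible: bool = False,
    with_providers: bool = True,
) -> list[IndicatorResult]:
    """Evaluate every cataloged indicator; infeasible ones get a notice.

    ``n_providers`` defaults to the number of distinct providers observed in
    the event tables.
    """
    index = EventIndex(events)
    if n_providers is None:
        provs = set()
        for table in EVENT_TABLES:
            df = events.get(table)
            if df is not None and len(df):
                provs.update(df["provider_id"].unique())
        n_providers = max(len(provs), 1)
    out = []
    for defn in catalog:
        feasible, reason = check_feasibility(defn, events, n_providers, min_provider_fraction)
        if not feasible and not force_infeasible:
            out.append(
                IndicatorResult(
                    id=defn.id,
                    short_name=defn.short_name,
                    numerator=0,
                    denominator=0,
                    feasible=False,
                    reason=reason,
                    year=defn.year,
                )
            )
            continue
        res = evaluate(defn, cohort, index, censor_date, catalog, with_providers=with_providers)
        res.feasible = feasible
        res.reason = reason
        out.append(res)
    return out


def patient_level(
    defn: IndicatorDefinition,
    cohort: pd.DataFrame,
    events: dict[str, pd.DataFrame] | EventIndex,
    censor_date,
    catalog: IndicatorCatalog,
) -> pd.DataFrame:
    """Patient-level outcomes for one indicator's denominator members.

    Returns one row per eligible patient with the binary outcome, the
    attributed provider and the case-mix covariates used by the
    reliability model.
    """
    index = events if isinstance(events, EventIndex) else EventIndex(events)
    censor = to_day(censor_date)
    evaluator = catalog.evaluator
    rows = []
    for ctx in _contexts(cohort, index, censor, evaluator.code_groups):
        if not evaluator.evaluate(defn.denominator, ctx):
            continue
        rows.append(
            {
                "patient_id": ctx.patient_id,
                "outcome": int(evaluator.evaluate(defn.numerator, ctx)),
                "provider": _attributed_provider(defn, ctx, evaluator),
                "age_stratum": ctx.row.age_stratum,
                "sex": ctx.row.sex,
                "stage_group": ctx.row.stage_group,
                "charlson_class": ctx.row.charlson_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "outcome", "provider", "age_stratum", "sex", "stage_group", "charlson_class"],
    )


def clinimetrics(result: IndicatorResult) -> dict:
    """Provider-distribution summary: improvement potential and floor/ceiling.

    Quartiles use linear interpolation between order statistics.  Floor and
    ceiling count providers at exactly 0% and exactly 100%.
    """
    if result.providers is None or len(result.providers) == 0:
        return {
            "n_providers": 0, "floor": 0, "ceiling": 0,
            "mean": float("nan"), "sd": float("nan"),
            "median": float("nan"), "q1": float("nan"), "q3": float("nan"),
        }
    p = result.providers["p"].to_numpy(dtype=float)
    return {
        "n_providers": int(len(p)),
        "floor": int(np.sum(p == 0.0)),
        "ceiling": int(np.sum(p == 100.0)),
        "mean": float(np.mean(p)),
        "sd": float(np.std(p, ddof=1)) if len(p) > 1 else 0.0,
        "median": float(np.percentile(p, 50)),
        "q1": float(np.percentile(p, 25)),
        "q3": float(np.percentile(p, 75)),
    }
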