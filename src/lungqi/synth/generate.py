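"""Synthetic linked-database generation and per-indicator calibration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from lungqi.errors import CalibrationError, SpecValidationError
from lungqi.indicators.model import from_day, to_day
from lungqi.synth.allocate import allocate
from lungqi.synth.events import plan_events
from lungqi.synth.spec import CohortSpec

REGISTRY_COLUMNS = [
    "patient_id", "sex", "birth_date", "incidence_date", "topography",
    "morphology", "confirmed", "stage", "dco", "death_date",
]
EVENT_COLUMNS = ["patient_id", "provider_id", "date", "code"]


@dataclasses.dataclass
class GeneratedData:
    """The five linked synthetic tables plus generation metadata."""

    registry: pd.DataFrame
    events: dict[str, pd.DataFrame]
    sidecar: dict
    provider_effects: dict[str, float]

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {"registry": self.registry, **self.events}

    def write(self, out_dir) -> None:
        """Write the five CSV files and the JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "sidecar.json", "w") as fh:
            json.dump(self.sidecar, fh, indent=2, default=str)


def generate_provider_effects(n_providers: int, tau2: float, seed: int) -> dict[str, float]:
    """Draw i.i.d. mean-zero provider log-odds offsets with variance ``tau2``."""
    if tau2 < 0:
        raise SpecValidationError("tau2", "variance must be non-negative")
    rng = np.random.default_rng(seed)
    draws = rng.normal(0.0, np.sqrt(tau2), size=n_providers) if tau2 > 0 else np.zeros(n_providers)
    return {f"P{j + 1:03d}": float(d) for j, d in enumerate(draws)}


def _empty_tables() -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    registry = pd.DataFrame(columns=REGISTRY_COLUMNS)
    events = {
        "inpatient": pd.DataFrame(columns=EVENT_COLUMNS + ["discharge_date"]),
        "outpatient": pd.DataFrame(columns=EVENT_COLUMNS),
        "prescriptions": pd.DataFrame(columns=EVENT_COLUMNS),
        "emergency": pd.DataFrame(columns=EVENT_COLUMNS),
    }
    return registry, events


def generate(spec: Optional[CohortSpec] = None) -> GeneratedData:
    """Generate the five linked tables with the statistical structure of
    the pilot cohort, calibrated to the spec's indicator targets.

    Deterministic for a fixed spec (the seed lives on the spec).  Raises
    :class:`~lungqi.errors.CalibrationError` when the targets are jointly
    infeasible.
    """
    spec = (spec or CohortSpec()).validate()
    if spec.n_patients == 0:
        registry, events = _empty_tables()
        sidecar = {"spec": spec.to_dict(), "seed": spec.seed, "notes": {"deviations": []}}
        return GeneratedData(registry, events, sidecar, {})

    profiles, notes = allocate(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    sparse_providers = ["P001", "P002"][: max(1, min(2, spec.n_providers))]

    # ---- registry -------------------------------------------------------
    def registry_rows(df: pd.DataFrame) -> pd.DataFrame:
        birth = df["inc"] - (df["age"] * 365.25).astype(int) - 180
        out = pd.DataFrame(
            {
                "patient_id": df["patient_id"],
                "sex": df["sex"],
                "birth_date": [from_day(int(b)) for b in birth],
                "incidence_date": [from_day(int(d)) for d in df["inc"]],
                "topography": np.where(np.arange(len(df)) % 50 == 0, "C33", "C34.1"),
                "morphology": df["morphology"],
                "confirmed": df["confirmed"].astype(bool),
                "stage": df["stage"],
                "dco": False,
                "death_date": [from_day(None if pd.isna(d) else int(d)) for d in df["death"]],
            }
        )
        return out

    registry = registry_rows(profiles)

    # excluded cases: death-certificate-only and mesenchymal histology
    extra_rows = []
    epoch_year = spec.years[0]
    for i in range(spec.dco_count + spec.mesenchymal_count):
        is_dco = i < spec.dco_count
        inc = to_day(f"{epoch_year + i % (spec.years[1] - spec.years[0] + 1)}-06-15")
        extra_rows.append(
            {
                "patient_id": f"PX{i + 1:05d}",
                "sex": "M" if i % 4 else "F",
                "birth_date": from_day(inc - 70 * 365 - 100),
                "incidence_date": from_day(inc),
                "topography": "C34.1",
                "morphology": np.nan if is_dco else 8800,
                "confirmed": not is_dco,
                "stage": None,
                "dco": is_dco,
                "death_date": from_day(inc) if is_dco else pd.NaT,
            }
        )
    if extra_rows:
        registry = pd.concat([registry, pd.DataFrame(extra_rows)], ignore_index=True)

    # ---- events ---------------------------------------------------------
    planned: dict[str, list] = {t: [] for t in ("inpatient", "outpatient", "prescriptions", "emergency")}
    for r in profiles.itertuples(index=False):
        sparse = sparse_providers[int(rng.integers(0, len(sparse_providers)))]
        for table, day, code, provider, discharge in plan_events(r, sparse):
            row = {
                "patient_id": r.patient_id,
                "provider_id": provider,
                "date": from_day(day),
                "code": code,
            }
            if table == "inpatient":
                row["discharge_date"] = from_day(discharge) if discharge is not None else pd.NaT
            planned[table].append(row)

    events = {}
    for table, rows in planned.items():
        cols = EVENT_COLUMNS + (["discharge_date"] if table == "inpatient" else [])
        df = pd.DataFrame(rows, columns=cols)
        df = df.sort_values(["patient_id", "date", "code"], kind="stable").reset_index(drop=True)
        events[table] = df

    sidecar = {
        "spec": spec.to_dict(),
        "seed": spec.seed,
        "notes": notes["deviations"],
        "realized": notes["realized"],
    }
    return GeneratedData(registry, events, sidecar, notes["provider_effects"])


# --------------------------------------------------------------------------- #
# per-indicator post-hoc calibration                                           #
# --------------------------------------------------------------------------- #


def _cohort_for(tables: dict[str, pd.DataFrame]):
    from lungqi.cohort import build_cohort, derive_covariates

    retained, _ = build_cohort(tables["registry"])
    events = {k: v for k, v in tables.items() if k != "registry"}
    return derive_covariates(retained, events), events


def _patient_home_provider(events: dict[str, pd.DataFrame], patient_id: str) -> str:
    for df in events.values():
        hit = df[df["patient_id"] == patient_id]
        if len(hit):
            return str(hit["provider_id"].iloc[0])
    return "P001"


class _NumeratorEditor:
    """Adds or removes the events that decide a numerator predicate."""

    def __init__(self, catalog, events, censor):
        self.ev = catalog.evaluator
        self.events = events
        self.censor = censor

    def _window_days(self, node, ctx):
        anchor = ctx.anchors.get(node.get("anchor")) if node.get("anchor") else None
        if node.get("anchor") and anchor is None:
            raise CalibrationError(
                f"cannot place event for {ctx.patient_id}: anchor {node['anchor']!r} missing"
            )
        lo = anchor + int(node["lo"]) if anchor is not None and "lo" in node else None
        hi = anchor + int(node["hi"]) if anchor is not None and "hi" in node else None
        return lo, hi

    def _add_event(self, node, ctx):
        codes = self.ev.resolve_codes(node.get("codes"))
        if node.get("only"):
            codes = self.ev.resolve_codes(node["only"])
        code = sorted(codes)[0]
        lo, hi = self._window_days(node, ctx)
        if lo is None and hi is None:
            day = ctx.incidence
        else:
            day = (lo + hi) // 2 if lo is not None and hi is not None else (lo or hi)
        table = "outpatient"
        provider = _patient_home_provider(self.events, ctx.patient_id)
        self.events[table] = pd.concat(
            [
                self.events[table],
                pd.DataFrame(
                    [{"patient_id": ctx.patient_id, "provider_id": provider,
                      "date": from_day(day), "code": code}]
                ),
            ],
            ignore_index=True,
        )

    def _remove_events(self, node, ctx):
        codes = self.ev.resolve_codes(node.get("codes"))
        if node.get("only"):
            codes = self.ev.resolve_codes(node["only"])
        lo, hi = self._window_days(node, ctx)
        for table, df in self.events.items():
            if not len(df):
                continue
            day = pd.to_datetime(df["date"]).map(to_day)
            mask = df["patient_id"] == ctx.patient_id
            if codes is not None:
                mask &= df["code"].isin(codes)
            if lo is not None:
                mask &= day >= lo
            if hi is not None:
                mask &= day <= hi
            if mask.any():
                self.events[table] = df[~mask].reset_index(drop=True)

    def make(self, node, ctx, value: bool):
        (op, arg), = node.items()
        current = self.ev.evaluate(node, ctx)
        if current == value:
            return
        if op == "has_event":
            self._add_event(arg, ctx) if value else self._remove_events(arg, ctx)
        elif op == "no_event":
            self._remove_events(arg, ctx) if value else self._add_event(arg, ctx)
        elif op == "all_of":
            if value:
                for child in arg:
                    self.make(child, ctx, True)
            else:
                for child in arg:
                    if next(iter(child)) in ("has_event", "no_event", "first_contact_within"):
                        self.make(child, ctx, False)
                        return
                raise CalibrationError(f"cannot falsify numerator for {ctx.patient_id}")
        elif op == "any_of":
            if value:
                self.make(arg[0], ctx, True)
            else:
                for child in arg:
                    self.make(child, ctx, False)
        elif op == "first_contact_within":
            ft = ctx.anchors.get("first_therapy")
            if ft is None:
                raise CalibrationError(f"{ctx.patient_id}: no first therapy to anchor the contact window")
            if value:
                self._remove_events({"lo": -self.ev.contact_lookback, "hi": -int(arg["days"]) - 1,
                                     "anchor": "first_therapy"}, ctx)
                self._add_event({"codes": ["GP_VISIT"], "anchor": "first_therapy",
                                 "lo": -30, "hi": -30}, ctx)
            else:
                self._add_event({"codes": ["GP_VISIT"], "anchor": "first_therapy",
                                 "lo": -self.ev.contact_lookback, "hi": -self.ev.contact_lookback}, ctx)
        else:
            raise CalibrationError(
                f"numerator operator {op!r} is registry-determined and cannot be event-calibrated"
            )


def calibrate_indicator(
    tables: dict[str, pd.DataFrame],
    indicator_id: str,
    target: tuple[int, int],
    censor_date="2016-12-31",
    catalog=None,
) -> dict[str, pd.DataFrame]:
    """Adjust the event tables so one indicator reports exactly ``target``.

    Only numerator membership is adjusted (by adding or removing the events
    the numerator predicate tests); the denominator must already match the
    target, otherwise the target is declared infeasible.  Returns a new
    table dict; the input is not modified.
    """
    from lungqi.indicators.engine import EventIndex, evaluate
    from lungqi.indicators.model import PatientCtx
    from lungqi.resources import load_catalog

    catalog = catalog or load_catalog()
    if indicator_id not in catalog:
        raise KeyError(f"unknown indicator {indicator_id!r}")
    defn = catalog[indicator_id]
    k_target, n_target = int(target[0]), int(target[1])
    if not 0 <= k_target <= n_target:
        raise CalibrationError("target numerator must lie in [0, denominator]")

    tables = {k: v.copy() for k, v in tables.items()}
    cohort, events = _cohort_for(tables)
    censor = to_day(censor_date)
    groups = catalog.evaluator.code_groups

    index = EventIndex(events)
    members, successes = [], []
    for row in cohort.itertuples(index=False):
        ctx = PatientCtx(row, index.events_for(row.patient_id), censor, groups)
        if catalog.evaluator.evaluate(defn.denominator, ctx):
            members.append(row)
            successes.append(catalog.evaluator.evaluate(defn.numerator, ctx))
    if len(members) != n_target:
        raise CalibrationError(
            f"{indicator_id}: target denominator {n_target} but cohort yields {len(members)} "
            "eligible patients (denominators are fixed by the cohort structure)"
        )

    editor = _NumeratorEditor(catalog, events, censor)
    current = sum(successes)
    if current > k_target:
        flip = [m for m, s in zip(members, successes) if s][: current - k_target]
        want = False
    else:
        flip = [m for m, s in zip(members, successes) if not s][: k_target - current]
        want = True
    for row in flip:
        index = EventIndex(editor.events)
        ctx = PatientCtx(row, index.events_for(row.patient_id), censor, groups)
        editor.make(defn.numerator, ctx, want)

    out = {"registry": tables["registry"], **editor.events}
    cohort2, events2 = _cohort_for(out)
    res = evaluate(defn, cohort2, events2, censor_date, catalog, with_providers=False)
    if (res.numerator, res.denominator) != (k_target, n_target):
        raise CalibrationError(
            f"{indicator_id}: calibration landed at {res.numerator}/{res.denominator}, "
            f"target {k_target}/{n_target}"
        )
    return out
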