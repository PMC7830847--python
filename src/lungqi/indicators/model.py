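"""Declarative indicator definitions and their predicate language.

An indicator is a pair of predicates over a patient and their linked
health-care events: the *denominator* predicate selects eligible patients
and the *numerator* predicate — evaluated only for denominator members —
decides success.  Predicates are composed from a small set of primitives
(`has_event`, `stage_in`, `received_chemoradiation`, ...) so that the whole
catalog is data, auditable row by row against its clinical description.

All time windows are expressed in days relative to a per-patient anchor
date (incidence, first therapy, first surgery, its discharge, first biopsy,
or death) and are inclusive of both endpoints.  Dates are handled
internally as integer day numbers.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Iterable, Optional

import numpy as np
import pandas as pd

from lungqi.errors import ConfigurationError

#: tables an event can come from
EVENT_TABLES = ("inpatient", "outpatient", "prescriptions", "emergency")

_DAY0 = np.datetime64("1970-01-01", "D")


def to_day(value) -> Optional[int]:
    """Convert a date-like value to an integer day number (None for missing)."""
    if value is None:
        return None
    if isinstance(value, (int, np.integer)):
        return int(value)
    ts = pd.Timestamp(value)
    if pd.isna(ts):
        return None
    return int((np.datetime64(ts.date(), "D") - _DAY0).astype(int))


def from_day(day: Optional[int]):
    if day is None:
        return pd.NaT
    return pd.Timestamp(_DAY0 + np.timedelta64(int(day), "D"))


@dataclasses.dataclass(frozen=True)
class Event:
    day: int
    code: str
    table: str
    provider: str
    discharge_day: Optional[int] = None


STAGE_GROUPS = {"IA": "I", "IB": "I", "IIA": "II", "IIB": "II", "IIIA": "III", "IIIB": "III"}


def stage_group(stage: Optional[str]) -> Optional[str]:
    """Collapse a detailed stage label (e.g. IIIA) to its I-IV group."""
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return None
    return STAGE_GROUPS.get(stage, stage)


def stage_matches(stage: Optional[str], wanted: Iterable[str]) -> bool:
    """True if the patient's (detailed) stage falls in any wanted label.

    Group labels (I, II, III, IV) match all their substages; substage labels
    (IIA, IIIA, ...) match exactly.  A missing stage matches nothing.
    """
    if stage is None:
        return False
    grp = stage_group(stage)
    for w in wanted:
        if w in ("I", "II", "III", "IV"):
            if grp == w:
                return True
        elif stage == w:
            return True
    return False


class PatientCtx:
    """Evaluation context: one patient's covariates, events and anchor dates."""

    __slots__ = (
        "patient_id", "incidence", "death", "stage", "histology", "confirmed",
        "first_therapy", "first_therapy_day", "events", "anchors", "censor",
        "row",
    )

    def __init__(self, row, events: list[Event], censor: int, code_groups: dict):
        self.row = row
        self.patient_id = row.patient_id
        self.incidence = to_day(row.incidence_date)
        self.death = to_day(row.death_date)
        self.stage = None if pd.isna(row.stage) else row.stage
        self.histology = row.histology
        self.confirmed = bool(row.confirmed)
        self.first_therapy = row.first_therapy
        self.first_therapy_day = to_day(row.first_therapy_date)
        self.events = events  # sorted by (day, table, code)
        self.censor = censor
        self.anchors = self._build_anchors(code_groups)

    def _build_anchors(self, code_groups: dict) -> dict:
        surgery_codes = set(code_groups["lung_surgery"])
        biopsy_codes = set(code_groups["biopsy"])
        first_surgery = None
        discharge = None
        first_biopsy = None
        for ev in self.events:
            if first_surgery is None and ev.code in surgery_codes:
                first_surgery = ev.day
                discharge = ev.discharge_day
            if (
                first_biopsy is None
                and ev.code in biopsy_codes
                and self.incidence is not None
                and self.incidence - 90 <= ev.day <= self.incidence + 30
            ):
                first_biopsy = ev.day
            if first_surgery is not None and first_biopsy is not None:
                break
        return {
            "incidence": self.incidence,
            "first_therapy": self.first_therapy_day,
            "first_surgery": first_surgery,
            "first_surgery_discharge": discharge,
            "first_biopsy": first_biopsy,
            "death": self.death,
        }

    # -- event scans ------------------------------------------------------
    def events_matching(self, codes: Optional[set], tables: Optional[set],
                        lo: Optional[int], hi: Optional[int]) -> Iterable[Event]:
        for ev in self.events:
            if codes is not None and ev.code not in codes:
                continue
            if tables is not None and ev.table not in tables:
                continue
            if lo is not None and ev.day < lo:
                continue
            if hi is not None and ev.day > hi:
                continue
            yield ev

    def first_event_day(self) -> Optional[int]:
        return self.events[0].day if self.events else None


class PredicateEvaluator:
    """Evaluates a predicate tree against a :class:`PatientCtx`."""

    def __init__(self, code_groups: dict, known_codes: set, contact_lookback: int = 180):
        self.code_groups = code_groups
        self.known_codes = known_codes
        self.contact_lookback = contact_lookback

    # -- code resolution --------------------------------------------------
    def resolve_codes(self, spec) -> Optional[set]:
        """Resolve a group name / token list to a set of tokens (None = any)."""
        if spec is None:
            return None
        if isinstance(spec, str):
            if spec in self.code_groups:
                return set(self.code_groups[spec])
            if spec in self.known_codes:
                return {spec}
            raise ConfigurationError(f"unknown code token or group: {spec!r}")
        out = set()
        for tok in spec:
            if tok in self.code_groups:
                out.update(self.code_groups[tok])
            elif tok in self.known_codes:
                out.add(tok)
            else:
                raise ConfigurationError(f"unknown code token: {tok!r}")
        return out

    def _window(self, node: dict, ctx: PatientCtx):
        """Return (lo, hi) absolute day bounds, or ``missing`` sentinel."""
        anchor_name = node.get("anchor")
        if anchor_name is None:
            return None, None, True
        anchor = ctx.anchors.get(anchor_name)
        if anchor is None:
            return None, None, False
        lo = anchor + int(node["lo"]) if "lo" in node else None
        hi = anchor + int(node["hi"]) if "hi" in node else None
        return lo, hi, True

    # -- evaluation -------------------------------------------------------
    def evaluate(self, node: Any, ctx: PatientCtx) -> bool:
        if node is None:
            return True
        if not isinstance(node, dict) or len(node) != 1:
            raise ConfigurationError(f"malformed predicate node: {node!r}")
        (op, arg), = node.items()
        fn = getattr(self, f"_op_{op}", None)
        if fn is None:
            raise ConfigurationError(f"unknown predicate operator: {op!r}")
        return fn(arg, ctx)

    def _op_all(self, arg, ctx):
        return True

    def _op_all_of(self, arg, ctx):
        return all(self.evaluate(child, ctx) for child in arg)

    def _op_any_of(self, arg, ctx):
        return any(self.evaluate(child, ctx) for child in arg)

    def _op_not(self, arg, ctx):
        return not self.evaluate(arg, ctx)

    def _op_has_event(self, arg, ctx):
        codes = self.resolve_codes(arg.get("codes"))
        only = arg.get("only")
        if only is not None:
            codes = self.resolve_codes(only) if codes is None else codes & self.resolve_codes(only)
        tables = set(arg["tables"]) if arg.get("tables") else None
        lo, hi, anchored = self._window(arg, ctx)
        if not anchored:
            return False
        for _ in ctx.events_matching(codes, tables, lo, hi):
            return True
        return False

    def _op_no_event(self, arg, ctx):
        return not self._op_has_event(arg, ctx)

    def _op_has_contact(self, arg, ctx):
        lo, hi, anchored = self._window(arg, ctx)
        if not anchored:
            return False
        for _ in ctx.events_matching(None, None, lo, hi):
            return True
        return False

    def _op_first_contact_within(self, arg, ctx):
        """First recorded contact no more than `days` before first therapy.

        The first contact is the earliest event of any kind in the
        contact-lookback window that precedes the first therapy date.
        """
        ft = ctx.anchors["first_therapy"]
        if ft is None:
            return False
        first = None
        for ev in ctx.events_matching(None, None, ft - self.contact_lookback, ft - 1):
            first = ev.day
            break
        if first is None:
            return False
        return ft - first <= int(arg["days"])

    def _op_stage_in(self, arg, ctx):
        return stage_matches(ctx.stage, arg)

    def _op_histology(self, arg, ctx):
        return ctx.histology == arg

    def _op_treated(self, arg, ctx):
        return (ctx.first_therapy != "none") == bool(arg)

    def _op_first_therapy_in(self, arg, ctx):
        return ctx.first_therapy in arg

    def _op_confirmed(self, arg, ctx):
        return ctx.confirmed == bool(arg)

    def _op_deceased_by_censor(self, arg, ctx):
        dead = ctx.death is not None and ctx.death <= ctx.censor
        return dead == bool(arg)

    def _op_not_deceased_within(self, arg, ctx):
        anchor = ctx.anchors.get(arg["anchor"])
        if anchor is None:
            return False
        return ctx.death is None or ctx.death > anchor + int(arg["days"])

    def _op_alive_after_days(self, arg, ctx):
        days = int(arg["days"])
        return ctx.death is None or ctx.death > ctx.incidence + days

    def _op_received_chemoradiation(self, arg, ctx):
        """Both chemotherapy and radiotherapy received; optionally the two
        modalities must each start within `max_gap` days of the other."""
        chemo = self.resolve_codes("chemo")
        rt = self.resolve_codes("radiotherapy")
        first_c = first_r = None
        for ev in ctx.events:
            if first_c is None and ev.code in chemo:
                first_c = ev.day
            if first_r is None and ev.code in rt:
                first_r = ev.day
            if first_c is not None and first_r is not None:
                break
        if first_c is None or first_r is None:
            return False
        max_gap = arg.get("max_gap")
        if max_gap is None:
            return True
        return abs(first_c - first_r) <= int(max_gap)

    def _op_first_event_code_in(self, arg, ctx):
        family = self.resolve_codes(arg["family"])
        wanted = self.resolve_codes(arg["codes"])
        for ev in ctx.events:
            if ev.code in family:
                return ev.code in wanted
        return False

    def _op_stay_le(self, arg, ctx):
        start = ctx.anchors.get("first_surgery")
        end = ctx.anchors.get("first_surgery_discharge")
        if start is None or end is None:
            return False
        return end - start <= int(arg["days"])


@dataclasses.dataclass(frozen=True)
class IndicatorDefinition:
    """One indicator: eligibility and success predicates plus metadata."""

    id: str
    base_id: str
    section: str
    short_name: str
    denominator: dict
    numerator: dict
    required_codes: tuple = ()
    attribution: dict = dataclasses.field(default_factory=lambda: {"kind": "any_contact"})
    year: Optional[int] = None
    panel_added: bool = False


def _substitute_year(node, year: int):
    """Expand templated window expressions such as ``365*(year-1)+1``."""
    if isinstance(node, dict):
        return {k: _substitute_year(v, year) for k, v in node.items()}
    if isinstance(node, list):
        return [_substitute_year(v, year) for v in node]
    if isinstance(node, str) and "year" in node:
        return int(eval(node, {"__builtins__": {}}, {"year": year}))  # noqa: S307 - package-owned data
    return node


class IndicatorCatalog:
    """The full set of indicator definitions plus the predicate evaluator."""

    def __init__(self, definitions: list[IndicatorDefinition], evaluator: PredicateEvaluator):
        self.definitions = definitions
        self.evaluator = evaluator
        self._by_id = {d.id: d for d in definitions}

    @classmethod
    def from_dict(cls, raw: dict, codes: dict) -> "IndicatorCatalog":
        groups = codes["groups"]
        known = set(codes["codes"]) | set(codes.get("charlson", {}))
        evaluator = PredicateEvaluator(groups, known, raw.get("contact_lookback_days", 180))
        defs: list[IndicatorDefinition] = []
        for entry in raw["indicators"]:
            years = entry.get("years")
            if years:
                for y in years:
                    defs.append(
                        IndicatorDefinition(
                            id=f"{entry['id']}y{y}",
                            base_id=entry["id"],
                            section=entry["section"],
                            short_name=entry["short_name"].format(year=y),
                            denominator=_substitute_year(entry["denominator"], y),
                            numerator=_substitute_year(entry["numerator"], y),
                            required_codes=tuple(entry.get("required_codes", ())),
                            attribution=entry.get("attribution", {"kind": "any_contact"}),
                            year=y,
                        )
                    )
            else:
                defs.append(
                    IndicatorDefinition(
                        id=entry["id"],
                        base_id=entry["id"],
                        section=entry["section"],
                        short_name=entry["short_name"],
                        denominator=entry["denominator"],
                        numerator=entry["numerator"],
                        required_codes=tuple(entry.get("required_codes", ())),
                        attribution=entry.get("attribution", {"kind": "any_contact"}),
                        panel_added=bool(entry.get("panel_added", False)),
                    )
                )
        cat = cls(defs, evaluator)
        cat._validate_codes()
        return cat

    def _validate_codes(self):
        for d in self.definitions:
            for tok in d.required_codes:
                self.evaluator.resolve_codes([tok])

    def __iter__(self):
        return iter(self.definitions)

    def __len__(self):
        return len(self.definitions)

    def __getitem__(self, ind_id: str) -> IndicatorDefinition:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.definitions]

    @property
    def base_ids(self) -> list[str]:
        seen = []
        for d in self.definitions:
            if d.base_id not in seen:
                seen.append(d.base_id)
        return seen
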