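"""Independent brute-force implementations of every feasible indicator.

Each oracle is a literal transcription of the indicator's clinical rule,
evaluated patient by patient over the raw tables with plain loops; it
shares no code with the engine (its own anchor derivation, its own first
therapy logic) so that agreement between the two is evidence, not
tautology.
"""

from __future__ import annotations

import pandas as pd

D = lambda ts: (pd.Timestamp(ts) - pd.Timestamp("1970-01-01")).days  # noqa: E731

SURGERY = {"WEDGE_RESECTION", "SEGMENTECTOMY", "LOBECTOMY", "PNEUMONECTOMY"}
CURATIVE = {"SEGMENTECTOMY", "LOBECTOMY", "PNEUMONECTOMY"}
BIOPSY = {"BRONCHOSCOPY", "NEEDLE_BIOPSY"}
HEAD = {"CT_HEAD", "MR_HEAD"}
METS = {"PET", "BONE_SCAN"}
ABDO = {"CT_ABDOMEN", "US_ABDOMEN"}
FOLLOWUP = {"FOLLOWUP_VISIT", "PLANNED_ADMISSION"}


def patient_events(tables, pid):
    """All events of one patient as sorted (day, code, table, discharge)."""
    out = []
    for table in ("inpatient", "outpatient", "prescriptions", "emergency"):
        df = tables[table]
        for row in df[df["patient_id"] == pid].itertuples(index=False):
            dis = None
            if table == "inpatient" and not pd.isna(row.discharge_date):
                dis = D(row.discharge_date)
            out.append((D(row.date), str(row.code), table, dis))
    out.sort(key=lambda e: (e[0], e[2], e[1]))
    return out


class OraclePatient:
    """Registry attributes plus independently re-derived anchors."""

    def __init__(self, reg_row, events, censor_day):
        self.events = events
        self.inc = D(reg_row.incidence_date)
        self.death = None if pd.isna(reg_row.death_date) else D(reg_row.death_date)
        self.censor = censor_day
        morph = reg_row.morphology
        self.confirmed = bool(reg_row.confirmed)
        self.sclc = self.confirmed and not pd.isna(morph) and 8041 <= int(morph) <= 8045
        stage = None if pd.isna(reg_row.stage) else str(reg_row.stage)
        self.stage = stage
        self.stage_group = None if stage is None else {"IA": "I", "IB": "I", "IIA": "II", "IIB": "II",
                                                       "IIIA": "III", "IIIB": "III"}.get(stage, stage)
        # first therapy: earliest treatment event within 180 days of incidence
        chemo_days = [d for d, c, _, _ in events if c == "CHEMO"]
        rt_days = [d for d, c, _, _ in events if c == "RT_FRACTION"]
        surg = [(d, c) for d, c, _, _ in events if c in SURGERY]
        first_c = min([d for d in chemo_days if d >= self.inc], default=None)
        first_r = min([d for d in rt_days if d >= self.inc], default=None)
        first_s = min([d for d, _ in surg if d >= self.inc], default=None)
        candidates = [(d, k) for d, k in ((first_s, "surgery"), (first_c, "chemotherapy"),
                                          (first_r, "radiotherapy"))
                      if d is not None and self.inc <= d <= self.inc + 180]
        if not candidates:
            self.ft, self.ft_day = "none", None
        else:
            d0, kind = min(candidates)
            if kind == "surgery":
                self.ft, self.ft_day = "surgery", d0
            elif first_c is not None and first_r is not None and abs(first_c - first_r) <= 90:
                self.ft, self.ft_day = "chemoradiation", min(first_c, first_r)
            else:
                self.ft, self.ft_day = kind, d0
        # first surgery (any time) and its admission
        self.fs = min([d for d, _ in surg], default=None)
        self.fs_code = min([c for d, c in surg if d == self.fs], default=None) if surg else None
        self.fs_dis = None
        if self.fs is not None:
            for d, c, table, dis in events:
                if d == self.fs and c in SURGERY and table == "inpatient":
                    self.fs_dis = dis
                    break
        self.has_chemo = bool(chemo_days)
        self.has_rt = bool(rt_days)
        self.first_chemo = min(chemo_days, default=None)
        self.first_rt = min(rt_days, default=None)

    def any_in(self, codes, lo, hi, tables=None):
        for d, c, table, _ in self.events:
            if codes is not None and c not in codes:
                continue
            if tables is not None and table not in tables:
                continue
            if lo <= d <= hi:
                return True
        return False


def _contacts(p, lo, hi):
    return [d for d, _, _, _ in p.events if lo <= d <= hi]


def oracle_O1(p):
    if p.ft == "none" or p.ft_day is None:
        return False, False
    window = _contacts(p, p.ft_day - 180, p.ft_day - 1)
    if not window:
        return False, False
    return True, p.ft_day - min(window) <= 60


def oracle_O2(p):
    if p.fs is None or not p.any_in({"PET"}, p.fs - 90, p.fs - 1):
        return False, False
    return True, p.any_in({"PET"}, p.fs - 45, p.fs - 1)


def oracle_O4(p):
    if p.fs is None or not p.any_in({"CT_THORAX"}, p.fs - 90, p.fs - 1):
        return False, False
    return True, p.any_in({"CT_THORAX"}, p.fs - 45, p.fs - 1)


def oracle_D1(p):
    return True, p.any_in({"CT_THORAX"}, p.inc - 60, p.inc + 60)


def oracle_D2(p):
    biopsies = [d for d, c, _, _ in p.events if c in BIOPSY and p.inc - 90 <= d <= p.inc + 30]
    if not biopsies:
        return False, False
    fb = min(biopsies)
    return True, p.any_in({"CT_THORAX"}, fb - 30, fb)


def oracle_D3(p):
    if p.sclc or p.stage_group not in ("I", "II", "III"):
        return False, False
    if p.ft == "none" or p.ft_day is None:
        return True, False
    return True, p.any_in({"PET"}, p.ft_day - 90, p.ft_day - 1)


def oracle_D4(p):
    return True, p.confirmed


def oracle_D5(p):
    if p.sclc or p.stage_group != "III" or not (p.has_chemo and p.has_rt):
        return False, False
    if p.ft_day is None:
        return True, False
    head = p.any_in(HEAD, p.ft_day - 30, p.ft_day - 1)
    mets = p.any_in(METS, p.ft_day - 30, p.ft_day - 1)
    return True, head and mets


def oracle_D6(p):
    if not p.sclc:
        return False, False
    ok = all(
        p.any_in(group, p.inc - 90, p.inc)
        for group in ({"CT_THORAX"}, ABDO, HEAD, METS)
    )
    return True, ok


def oracle_S1(p):
    if p.fs is None:
        return False, False
    return True, p.death is None or p.death > p.fs + 30


def oracle_S2(p):
    if p.fs is None:
        return False, False
    return True, p.any_in({"CT_THORAX"}, p.fs - 30, p.fs - 1)


def oracle_S4(p):
    if p.sclc or p.stage is None or p.stage not in ("I", "IIA", "IIB", "IIIA"):
        return False, False
    return True, any(c in CURATIVE for _, c, _, _ in p.events)


def oracle_S5(p):
    if p.sclc or p.stage not in ("I", "IIA") or p.fs is None:
        return False, False
    return True, p.fs_code == "LOBECTOMY"


def oracle_S6(p):
    if p.fs is None:
        return False, False
    second = any(c in SURGERY and p.fs + 1 <= d <= p.fs + 30 for d, c, _, _ in p.events)
    return True, not second


def oracle_S7(p):
    if p.fs is None or p.fs_code not in CURATIVE:
        return False, False
    if p.fs_dis is None:
        return True, False
    short = p.fs_dis - p.fs <= 14
    access = p.any_in(None, p.fs_dis + 1, p.fs_dis + 30, tables={"inpatient", "emergency"})
    return True, short and not access


def oracle_M1(p):
    if p.sclc or p.stage_group not in ("II", "III") or p.fs is not None:
        return False, False
    ok = (
        p.first_chemo is not None
        and p.first_rt is not None
        and abs(p.first_chemo - p.first_rt) <= 90
    )
    return True, ok


def oracle_M2(p):
    if not p.sclc or p.stage_group == "IV":
        return False, False
    return True, p.has_chemo or p.has_rt


def oracle_M4(p):
    if p.death is None or p.death > p.censor:
        return False, False
    return True, p.any_in({"OPIOID_ATC"}, p.death - 90, p.death)


def _oracle_F1(p, year):
    alive = p.death is None or p.death > p.inc + 365 * year
    if not alive:
        return False, False
    return True, p.any_in(FOLLOWUP, p.inc + 365 * (year - 1) + 1, p.inc + 365 * year)


ORACLES = {
    "O1": oracle_O1,
    "O2": oracle_O2,
    "O4": oracle_O4,
    "D1": oracle_D1,
    "D2": oracle_D2,
    "D3": oracle_D3,
    "D4": oracle_D4,
    "D5": oracle_D5,
    "D6": oracle_D6,
    "S1": oracle_S1,
    "S2": oracle_S2,
    "S4": oracle_S4,
    "S5": oracle_S5,
    "S6": oracle_S6,
    "S7": oracle_S7,
    "M1": oracle_M1,
    "M2": oracle_M2,
    "M4": oracle_M4,
    "F1y2": lambda p: _oracle_F1(p, 2),
    "F1y3": lambda p: _oracle_F1(p, 3),
    "F1y4": lambda p: _oracle_F1(p, 4),
}

FEASIBLE_IDS = list(ORACLES)


def oracle_counts(tables, indicator_id, censor="2016-12-31"):
    """(numerator, denominator) by exhaustive per-patient evaluation."""
    fn = ORACLES[indicator_id]
    censor_day = D(censor)
    reg = tables["registry"]
    keep = ~reg["dco"].astype(bool) & ~reg["morphology"].map(
        lambda m: not pd.isna(m) and 8800 <= int(m) < 9000
    )
    num = den = 0
    for row in reg[keep].itertuples(index=False):
        p = OraclePatient(row, patient_events(tables, row.patient_id), censor_day)
        in_den, in_num = fn(p)
        den += in_den
        num += in_den and in_num
    return num, den
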