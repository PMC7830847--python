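"""Joint patient-profile allocation for the synthetic cohort.

The published per-indicator counts interlock: surgery indicators share one
denominator, early-stage NSCLC counts bound the lobectomy and curative
surgery targets, the treated-with-recent-contact denominator constrains
where diagnostic events may be placed, and the survival chain ties the
palliative/follow-up denominators together.  This module resolves all of
that *constructively*: it derives a full cross-classification of
(histology x detailed stage x first therapy x surgery subtype x event-lag
category x survival class) whose margins reproduce the calibration targets
exactly, checking feasibility at every step, and assigns each synthetic
patient one profile row.  Event placement from a profile is in
:mod:`lungqi.synth.events`.

Every failed constraint raises :class:`~lungqi.errors.CalibrationError`
naming the constraint, so infeasible target combinations are reported
rather than silently approximated.  The single knowingly unattainable
default is the follow-up year-4 denominator, which the published survival
chain forces to equal the number of patients alive at the censoring date;
the realized value is recorded in the allocation notes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lungqi.errors import CalibrationError
from lungqi.indicators.model import to_day
from lungqi.resources import load_milan_defaults
from lungqi.synth.spec import CohortSpec

_REFERENCE_CORE = 5746  # size of the published cohort the defaults refer to


def _check(cond: bool, constraint: str):
    if not cond:
        raise CalibrationError(f"infeasible calibration: {constraint}")


def largest_remainder(weights, total: int) -> list[int]:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0 or total == 0:
        return [0] * len(weights)
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def weighted_topk(candidates: list[int], k: int, logweights: np.ndarray, rng) -> list[int]:
    """Pick ``k`` of ``candidates`` favouring larger log-weights.

    Used to concentrate numerator successes at high-performing providers so
    that the calibrated cohort still carries between-provider signal.  The
    tie-break noise is logistic, so inclusion behaves like a unit-slope
    logistic threshold model in the log-weight at any selection fraction.
    """
    _check(k <= len(candidates), f"selection of {k} from pool of {len(candidates)}")
    if k == len(candidates):
        return list(candidates)
    keys = logweights[candidates] + rng.logistic(size=len(candidates))
    order = np.argsort(-keys, kind="stable")
    return [candidates[i] for i in order[:k]]


def complete_targets(spec: CohortSpec) -> dict[str, tuple[int, int]]:
    """Target map with any missing indicator filled from scaled defaults."""
    defaults = load_milan_defaults()["indicator_targets"]
    scale = spec.n_core / _REFERENCE_CORE
    out = {}
    for ind, (k, n) in defaults.items():
        n_s = round(n * scale)
        out[ind] = (min(n_s, round(k * scale)), n_s)
    out.update(spec.indicator_targets)
    return out


class _Pool:
    """Mutable pool of profile row indices for staged flag assignment."""

    def __init__(self, indices):
        self.indices = list(indices)

    def take(self, k: int, constraint: str, rng, logweights=None) -> list[int]:
        _check(0 <= k <= len(self.indices), f"{constraint} (need {k}, have {len(self.indices)})")
        if logweights is None:
            chosen = list(rng.choice(self.indices, size=k, replace=False)) if k else []
        else:
            chosen = weighted_topk(self.indices, k, logweights, rng)
        chosen_set = set(chosen)
        self.indices = [i for i in self.indices if i not in chosen_set]
        return chosen


def allocate(spec: CohortSpec):
    """Return (profiles DataFrame, notes dict) for the core cohort.

    The DataFrame has one row per retained patient with every registry
    attribute and every event-plan flag; DCO and mesenchymal rows are added
    later by the generator.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    n = spec.n_core
    notes: dict = {"deviations": []}
    T = complete_targets(spec)

    def tgt(ind):
        return T[ind]

    # ------------------------------------------------------------------ #
    # 1. scalar counts                                                    #
    # ------------------------------------------------------------------ #
    stage_cnt = dict(
        zip(
            ("I", "II", "III", "IV", "missing"),
            largest_remainder([spec.stage_probs[s] for s in ("I", "II", "III", "IV", "missing")], n),
        )
    )
    sclc_total = round(spec.sclc_frac * n)
    treat = dict(spec.treatment_counts)
    _check(sum(treat.values()) == n, "treatment counts must sum to the core cohort size")

    o1k, o1n = tgt("O1")
    o2k, o2n = tgt("O2")
    o4k, o4n = tgt("O4")
    d1k, d1n = tgt("D1")
    d2k, d2n = tgt("D2")
    d3k, d3n = tgt("D3")
    d4k, d4n = tgt("D4")
    d5k, d5n = tgt("D5")
    d6k, d6n = tgt("D6")
    s1k, s1n = tgt("S1")
    s2k, s2n = tgt("S2")
    s4k, s4n = tgt("S4")
    s5k, s5n = tgt("S5")
    s6k, s6n = tgt("S6")
    s7k, s7n = tgt("S7")
    m1k, m1n = tgt("M1")
    m2k, m2n = tgt("M2")
    m4k, m4n = tgt("M4")
    f2k, f2n = tgt("F1y2")
    f3k, f3n = tgt("F1y3")
    f4k, f4n = tgt("F1y4")

    surg_total = treat["surgery"]
    _check(d1n == n, "D1 denominator must equal the cohort size")
    _check(d4n == n, "D4 denominator must equal the cohort size")
    _check(d6n == sclc_total, "D6 denominator must equal the SCLC count")
    _check(s1n == surg_total and s2n == surg_total and s6n == surg_total,
           "S1/S2/S6 denominators must equal the surgery count")
    confirmed_total = d4k  # cyto-histologic confirmation count
    _check(sclc_total <= confirmed_total, "SCLC cases must be confirmed")

    # ------------------------------------------------------------------ #
    # 2. histology x detailed stage                                       #
    # ------------------------------------------------------------------ #
    sclc_iv = sclc_total - m2n
    _check(0 <= sclc_iv <= stage_cnt["IV"], "SCLC stage-IV count (M2 denominator vs SCLC total)")
    stage123 = stage_cnt["I"] + stage_cnt["II"] + stage_cnt["III"]
    sclc_123 = stage123 - d3n
    _check(0 <= sclc_123 <= m2n, "SCLC stage I-III count (D3 denominator vs stage totals)")
    sclc_miss = m2n - sclc_123
    _check(sclc_miss <= stage_cnt["missing"], "SCLC missing-stage count")
    sclc_I, sclc_II, sclc_III = largest_remainder(
        [stage_cnt["I"], stage_cnt["II"], stage_cnt["III"]], sclc_123
    )
    n_I = stage_cnt["I"] - sclc_I
    n_II = stage_cnt["II"] - sclc_II
    n_III = stage_cnt["III"] - sclc_III
    n_IIIb = d3n - s4n
    _check(0 <= n_IIIb <= n_III, "NSCLC IIIB count (D3 vs S4 denominators)")
    n_IIIa = n_III - n_IIIb
    n_IV = stage_cnt["IV"] - sclc_iv
    n_miss = stage_cnt["missing"] - sclc_miss
    _check(n_IV >= 0 and n_miss >= 0, "NSCLC stage IV / missing counts")

    # ------------------------------------------------------------------ #
    # 3. surgery structure                                                #
    # ------------------------------------------------------------------ #
    s23 = n_II + n_III - m1n
    _check(0 <= s23 <= surg_total, "surgery among NSCLC II-III (M1 denominator)")
    extra = min(12, max(0, surg_total - s23))  # surgeries outside NSCLC I-III
    s_I = surg_total - s23 - extra
    _check(0 <= s_I <= n_I, "surgery among NSCLC stage I")
    s_IIa = s5n - s_I
    _check(0 <= s_IIa <= s23, "surgery among NSCLC IIA (S5 denominator)")
    n_IIb = min(max(round(n_II * 0.10), 0), n_II - s_IIa)
    n_IIa = n_II - n_IIb
    _check(s_IIa <= n_IIa, "NSCLC IIA capacity for surgery")
    rest23 = s23 - s_IIa
    cur_out = s7n - s4k  # curative-type first surgeries outside NSCLC I-IIIA
    _check(cur_out >= 0, "S7 denominator vs S4 numerator")
    cur_extra = min(extra, cur_out)
    s_IIIb = cur_out - cur_extra
    _check(s_IIIb <= min(rest23, n_IIIb), "surgery among NSCLC IIIB")
    s_IIb = min(n_IIb, 20, rest23 - s_IIIb)
    s_IIIa = rest23 - s_IIIb - s_IIb
    _check(0 <= s_IIIa <= n_IIIa, "surgery among NSCLC IIIA")

    cur_IIb = s_IIb
    cur_IIIa = s_IIIa
    cur_I_IIa = s4k - cur_IIb - cur_IIIa
    _check(s5k <= cur_I_IIa <= s_I + s_IIa, "curative surgery among NSCLC I-IIA (S4/S5 numerators)")
    wedge_I_IIa = (s_I + s_IIa) - cur_I_IIa
    n_s1_fail = s1n - s1k
    n_s6_fail = s6n - s6k
    _check(n_s1_fail + n_s6_fail <= wedge_I_IIa + (extra - cur_extra),
           "early deaths and re-interventions need non-curative first surgeries")

    extra_sclc = min(2, extra, sclc_miss)
    extra_iv, extra_miss = largest_remainder([n_IV, n_miss], extra - extra_sclc)

    # ------------------------------------------------------------------ #
    # 4. medical treatment structure                                      #
    # ------------------------------------------------------------------ #
    crt_total, chemo_total, rt_total = treat["chemoradiation"], treat["chemotherapy"], treat["radiotherapy"]
    nonsurg_II = n_II - s_IIa - s_IIb
    nonsurg_III = n_III - s_IIIa - s_IIIb
    crt_II = min(m1k, max(0, round(m1k * 0.13)), nonsurg_II)
    crt_III = m1k - crt_II
    _check(crt_III <= nonsurg_III, "chemo-radiation among NSCLC III (M1 numerator)")
    # D5 denominator: NSCLC III receiving both chemo and RT in any sequence
    y_crt_after_surgery = min(s_IIIa + s_IIIb, max(0, round((d5n - crt_III) * 0.17)))
    z_late_rt = d5n - crt_III - y_crt_after_surgery
    _check(0 <= z_late_rt <= nonsurg_III - crt_III, "NSCLC III chemo-with-late-RT (D5 denominator)")
    chemo_only_III = min(nonsurg_III - crt_III - z_late_rt, max(0, round(z_late_rt * 0.66)))
    chemo_III = z_late_rt + chemo_only_III
    rt_III = min(nonsurg_III - crt_III - chemo_III, max(0, round(rt_total * 0.255)))
    none_III = nonsurg_III - crt_III - chemo_III - rt_III
    rt_II = min(nonsurg_II - crt_II, max(0, round(rt_total * 0.032)))
    none_II = nonsurg_II - crt_II - rt_II
    none_I = n_I - s_I
    _check(none_I >= 0 and none_II >= 0 and none_III >= 0, "untreated counts in NSCLC I-III")

    # SCLC treatment: M2 numerator = non-IV SCLC receiving chemo and/or RT
    sclc_nonIV_pool = m2n - extra_sclc
    _check(m2k <= sclc_nonIV_pool, "M2 numerator vs non-IV SCLC pool")
    crt_sclc = min(max(0, round(m2k * 0.14)), crt_total - crt_II - crt_III)
    chemo_sclc = min(max(0, round(m2k * 0.70)), m2k - crt_sclc)
    rt_sclc = m2k - crt_sclc - chemo_sclc
    none_sclc_nonIV = sclc_nonIV_pool - m2k
    chemo_sclc_iv = min(sclc_iv, max(0, round(sclc_iv * 0.725)))
    none_sclc_iv = sclc_iv - chemo_sclc_iv

    crt_IVm = crt_total - crt_II - crt_III - crt_sclc
    chemo_IVm = chemo_total - chemo_III - chemo_sclc - chemo_sclc_iv
    rt_IVm = rt_total - rt_II - rt_III - rt_sclc
    _check(crt_IVm >= 0 and chemo_IVm >= 0 and rt_IVm >= 0,
           "treatment totals vs stage-specific allocations")
    pool_IVm = (n_IV - extra_iv) + (n_miss - extra_miss)
    none_IVm = pool_IVm - crt_IVm - chemo_IVm - rt_IVm
    _check(none_IVm >= 0, "untreated count among NSCLC IV/missing")
    none_realized = none_I + none_II + none_III + none_IVm + none_sclc_nonIV + none_sclc_iv
    _check(none_realized == treat["none"], "untreated total must match the treatment marginal")

    # ------------------------------------------------------------------ #
    # 5. build profile rows (histology, stage, treatment)                 #
    # ------------------------------------------------------------------ #
    rows: list[dict] = []

    def add(count, histology, stage, treatment, **flags):
        for _ in range(int(count)):
            rows.append({"histology": histology, "stage": stage, "treatment": treatment, **flags})

    add(s_I, "NSCLC", "I", "surgery")
    add(none_I, "NSCLC", "I", "none")
    add(s_IIa, "NSCLC", "IIA", "surgery")
    add(s_IIb, "NSCLC", "IIB", "surgery")
    crt_IIa, crt_IIb_ = largest_remainder([n_IIa - s_IIa, n_IIb - s_IIb], crt_II)
    rt_IIa, rt_IIb_ = largest_remainder([n_IIa - s_IIa - crt_IIa, n_IIb - s_IIb - crt_IIb_], rt_II)
    add(crt_IIa, "NSCLC", "IIA", "chemoradiation")
    add(crt_IIb_, "NSCLC", "IIB", "chemoradiation")
    add(rt_IIa, "NSCLC", "IIA", "radiotherapy")
    add(rt_IIb_, "NSCLC", "IIB", "radiotherapy")
    add(n_IIa - s_IIa - crt_IIa - rt_IIa, "NSCLC", "IIA", "none")
    add(n_IIb - s_IIb - crt_IIb_ - rt_IIb_, "NSCLC", "IIB", "none")
    add(s_IIIa, "NSCLC", "IIIA", "surgery")
    add(s_IIIb, "NSCLC", "IIIB", "surgery")
    # split the non-surgical stage III treatment mix across IIIA/IIIB
    pool_a, pool_b = n_IIIa - s_IIIa, n_IIIb - s_IIIb
    for kind, total in (
        ("chemoradiation", crt_III),
        ("chemo_late_rt", z_late_rt),
        ("chemotherapy", chemo_only_III),
        ("radiotherapy", rt_III),
        ("none", none_III),
    ):
        ka, kb = largest_remainder([pool_a, pool_b], total)
        treatment = "chemotherapy" if kind == "chemo_late_rt" else kind
        add(ka, "NSCLC", "IIIA", treatment, late_rt=(kind == "chemo_late_rt"))
        add(kb, "NSCLC", "IIIB", treatment, late_rt=(kind == "chemo_late_rt"))
        pool_a, pool_b = pool_a - ka, pool_b - kb

    add(extra_iv, "NSCLC", "IV", "surgery")
    add(extra_miss, "NSCLC", None, "surgery")
    pool_iv, pool_m = n_IV - extra_iv, n_miss - extra_miss
    for kind, total in (
        ("chemoradiation", crt_IVm),
        ("chemotherapy", chemo_IVm),
        ("radiotherapy", rt_IVm),
        ("none", none_IVm),
    ):
        ka, kb = largest_remainder([pool_iv, pool_m], total)
        add(ka, "NSCLC", "IV", kind)
        add(kb, "NSCLC", None, kind)
        pool_iv, pool_m = pool_iv - ka, pool_m - kb

    # SCLC: distribute non-IV stages, then treatments within them
    add(extra_sclc, "SCLC", None, "surgery")
    sclc_cells = [("I", sclc_I), ("IIA", 0), ("IIB", 0), ("IIIA", 0), ("IIIB", 0), (None, sclc_miss - extra_sclc)]
    iia, iib = largest_remainder([1, 1], sclc_II)
    iiia, iiib = largest_remainder([1, 1], sclc_III)
    sclc_cells[1] = ("IIA", iia)
    sclc_cells[2] = ("IIB", iib)
    sclc_cells[3] = ("IIIA", iiia)
    sclc_cells[4] = ("IIIB", iiib)
    sclc_nonIV_rows = []
    for stage, cnt in sclc_cells:
        sclc_nonIV_rows.extend([stage] * cnt)
    alloc = (
        ["chemoradiation"] * crt_sclc
        + ["chemotherapy"] * chemo_sclc
        + ["radiotherapy"] * rt_sclc
        + ["none"] * none_sclc_nonIV
    )
    _check(len(alloc) == len(sclc_nonIV_rows), "SCLC non-IV treatment allocation")
    rng.shuffle(sclc_nonIV_rows)
    for stage, treatment in zip(sclc_nonIV_rows, alloc):
        add(1, "SCLC", stage, treatment)
    add(chemo_sclc_iv, "SCLC", "IV", "chemotherapy")
    add(none_sclc_iv, "SCLC", "IV", "none")

    _check(len(rows) == n, "profile rows must equal the core cohort size")
    df = pd.DataFrame(rows)
    if "late_rt" not in df:
        df["late_rt"] = False
    df["late_rt"] = df["late_rt"].where(df["late_rt"].notna(), False).astype(bool)
    for col in ("post_crt", "s1_fail", "s6_fail", "d1", "d2_den", "d2_num", "d3num",
                "d5num", "d6num", "mdt", "palliative", "m4num", "f1y2", "f1y3", "f1y4",
                "emergency_bg"):
        df[col] = False
    df["surgery_type"] = None
    df["o1"] = None
    df["ct_lag"] = np.nan
    df["pet_lag"] = np.nan
    df["s7"] = None
    df["death_class"] = None

    # ------------------------------------------------------------------ #
    # 6. providers and random effects                                     #
    # ------------------------------------------------------------------ #
    prov_ids = [f"P{j + 1:03d}" for j in range(spec.n_providers)]
    size_w = rng.lognormal(0.0, 0.5, size=spec.n_providers)
    provider_idx = rng.choice(spec.n_providers, size=n, p=size_w / size_w.sum())
    effects = rng.normal(0.0, np.sqrt(spec.tau2), size=spec.n_providers) if spec.tau2 > 0 else np.zeros(spec.n_providers)
    df["provider"] = [prov_ids[j] for j in provider_idx]
    logw = effects[provider_idx]  # per-patient log-weight for numerator picks

    surg_idx = df.index[df["treatment"] == "surgery"].tolist()
    nsclc123 = df["stage"].isin(["I", "IIA", "IIB", "IIIA", "IIIB"]) & (df["histology"] == "NSCLC")

    # ------------------------------------------------------------------ #
    # 7. surgery subtype, lag categories, adverse events                  #
    # ------------------------------------------------------------------ #
    def surg_pool(histology=None, stages=None, exclude=None):
        sel = df.index.isin(surg_idx)
        if histology is not None:
            sel &= df["histology"] == histology
        if stages is not None:
            sel &= df["stage"].isin(stages)
        if exclude is not None:
            sel &= ~df.index.isin(exclude)
        return df.index[sel].tolist()

    cur_pool = _Pool(surg_pool("NSCLC", ["I", "IIA"]))
    lob_idx = cur_pool.take(s5k, "lobectomies among NSCLC I-IIA surgery", rng, logw)
    df.loc[lob_idx, "surgery_type"] = "LOBECTOMY"
    seg_pne = cur_pool.take(cur_I_IIa - s5k, "curative surgery among NSCLC I-IIA", rng)
    half = len(seg_pne) // 2
    df.loc[seg_pne[:half], "surgery_type"] = "SEGMENTECTOMY"
    df.loc[seg_pne[half:], "surgery_type"] = "PNEUMONECTOMY"
    df.loc[cur_pool.indices, "surgery_type"] = "WEDGE_RESECTION"
    wedge_idx = list(cur_pool.indices)
    for stages, kind in ((["IIB"], "SEGMENTECTOMY"), (["IIIA"], "LOBECTOMY")):
        df.loc[surg_pool("NSCLC", stages), "surgery_type"] = kind
    df.loc[surg_pool("NSCLC", ["IIIB"]), "surgery_type"] = "LOBECTOMY"
    outside = surg_pool(stages=["IV"]) + surg_pool("NSCLC", [None]) + surg_pool("SCLC")
    outside = [i for i in outside if df.at[i, "surgery_type"] is None]
    df.loc[outside, "surgery_type"] = "LOBECTOMY"  # the `extra` curative-type surgeries

    fail_pool = _Pool(wedge_idx)
    df.loc[fail_pool.take(n_s1_fail, "peri-operative deaths on wedge surgeries", rng), "s1_fail"] = True
    df.loc[fail_pool.take(n_s6_fail, "30-day re-interventions on wedge surgeries", rng), "s6_fail"] = True

    # S7: curative-type first surgeries; numerator = short stay, no re-access
    s7_den_idx = [i for i in surg_idx if df.at[i, "surgery_type"] != "WEDGE_RESECTION"
                  and not df.at[i, "s1_fail"]]
    _check(len(s7_den_idx) == s7n, "S7 denominator (curative-type first surgeries)")
    s7_pool = _Pool(s7_den_idx)
    df.loc[s7_pool.take(s7k, "S7 numerator", rng, logw), "s7"] = "num"
    n_long = (s7n - s7k + 1) // 2
    df.loc[s7_pool.take(n_long, "S7 long stays", rng), "s7"] = "long"
    df.loc[s7_pool.indices, "s7"] = "readmit"

    # chemo+RT after surgery for part of the stage III surgical patients
    y_pool = _Pool(surg_pool("NSCLC", ["IIIA", "IIIB"]))
    y_idx = y_pool.take(y_crt_after_surgery, "post-surgery chemo-radiation in NSCLC III", rng)
    df.loc[y_idx, "post_crt"] = True

    # O1 membership for surgery patients (all are denominator members)
    forced_nonnum = max(o4n - o4k, o2n - o2k)
    _check(o1n >= surg_total, "O1 denominator must cover all surgery patients")
    o1num_surg = min(surg_total - forced_nonnum, round(o1k * surg_total / max(o1n, 1)))
    _check(0 <= o1num_surg <= o1k, "O1 numerator split between surgery and medical patients")
    o1_pool = _Pool(surg_idx)
    num_surg_idx = o1_pool.take(o1num_surg, "O1 numerator among surgery patients", rng, logw)
    df.loc[num_surg_idx, "o1"] = "num"
    nonnum_surg_idx = list(o1_pool.indices)
    df.loc[nonnum_surg_idx, "o1"] = "den"

    # thorax-CT / PET lag categories (NSCLC I-III surgery only)
    ct75, ct40, ct20 = o4n - o4k, o4k - s2k, s2k
    _check(ct40 >= 0 and ct20 >= 0, "O4 numerator vs S2 numerator")
    pet75, pet40 = o2n - o2k, o2k
    surg123 = set(surg_pool("NSCLC", ["I", "IIA", "IIB", "IIIA", "IIIB"]))
    _check(o4n <= len(surg123) and o2n <= len(surg123),
           "pre-surgery imaging targets vs NSCLC I-III surgery pool")
    nonnum123 = [i for i in nonnum_surg_idx if i in surg123]
    lag_pool = _Pool(nonnum123)
    ct75_idx = lag_pool.take(ct75, "thorax CT 46-90 days before surgery", rng)
    pet75_idx = ct75_idx[:pet75] if pet75 <= ct75 else ct75_idx + lag_pool.take(pet75 - ct75, "PET 46-90 days before surgery", rng)
    df.loc[ct75_idx, "ct_lag"] = 75
    df.loc[pet75_idx, "pet_lag"] = 75
    free123 = [i for i in surg123 if np.isnan(df.at[i, "ct_lag"])]
    free_pool = _Pool(free123)
    df.loc[free_pool.take(ct20, "thorax CT <=30 days before surgery", rng, logw), "ct_lag"] = 20
    df.loc[free_pool.take(ct40, "thorax CT 31-45 days before surgery", rng, logw), "ct_lag"] = 40
    pet_free = [i for i in surg123 if np.isnan(df.at[i, "pet_lag"])]
    df.loc[_Pool(pet_free).take(pet40, "PET <=45 days before surgery", rng, logw), "pet_lag"] = 40

    # ------------------------------------------------------------------ #
    # 8. medical-patient flags                                            #
    # ------------------------------------------------------------------ #
    treated_mask = df["treatment"] != "none"
    nonsurg_treated = df.index[treated_mask & (df["treatment"] != "surgery")].tolist()

    d3_extra = d3k - o2n
    _check(d3_extra >= 0, "D3 numerator must cover all PET-before-surgery patients")
    d3_pool = _Pool([i for i in nonsurg_treated if nsclc123[i]])
    df.loc[d3_pool.take(d3_extra, "PET before medical first therapy (D3)", rng, logw), "d3num"] = True

    d5_members = (
        y_idx
        + df.index[(df["treatment"] == "chemoradiation") & nsclc123 & df["stage"].isin(["IIIA", "IIIB"])].tolist()
        + df.index[df["late_rt"]].tolist()
    )
    _check(len(d5_members) == d5n, "D5 denominator (NSCLC III receiving chemo and RT)")
    df.loc[_Pool(d5_members).take(d5k, "D5 numerator", rng, logw), "d5num"] = True

    # O1 'out' (treated, no contact within 180 days): medical patients whose
    # profile forces no pre-therapy event
    protected = set(df.index[df["d3num"] | df["d5num"]])
    out_quota = (n - treat["none"]) - o1n
    _check(out_quota >= 0, "O1 denominator cannot exceed the treated count")
    out_pool = _Pool([i for i in nonsurg_treated if i not in protected])
    df.loc[out_pool.take(out_quota, "treated patients without recent contact (O1)", rng), "o1"] = "out"
    o1num_med = o1k - o1num_surg
    med_den_pool = _Pool([i for i in nonsurg_treated if df.at[i, "o1"] is None])
    df.loc[med_den_pool.take(o1num_med, "O1 numerator among medical patients", rng, logw), "o1"] = "num"
    df.loc[med_den_pool.indices, "o1"] = "den"

    # D6: staging work-up for SCLC (never the surgical SCLC cases)
    d6_pool = _Pool(df.index[(df["histology"] == "SCLC") & (df["treatment"] != "surgery")].tolist())
    df.loc[d6_pool.take(d6k, "D6 numerator vs non-surgical SCLC pool", rng, logw), "d6num"] = True

    # D2: biopsy cohort drawn from untreated + medical patients
    d2_pool = _Pool(df.index[df["treatment"] != "surgery"].tolist())
    d2_den_idx = d2_pool.take(d2n, "D2 denominator (biopsied patients)", rng)
    df.loc[d2_den_idx, "d2_den"] = True
    df.loc[_Pool(d2_den_idx).take(d2k, "D2 numerator", rng, logw), "d2_num"] = True

    # D1: forced by any placed thorax CT, then filled to the target
    forced_d1 = set(df.index[df["ct_lag"].notna() | df["d2_num"] | df["d6num"]])
    _check(len(forced_d1) <= d1k, "D1 numerator vs thorax CTs forced by other indicators")
    fill_pool = _Pool([i for i in df.index
                       if i not in forced_d1 and not (df.at[i, "treatment"] == "surgery" and np.isnan(df.at[i, "ct_lag"]))])
    d1_fill = fill_pool.take(d1k - len(forced_d1), "D1 numerator fill", rng, logw)
    df.loc[list(forced_d1) + d1_fill, "d1"] = True

    # ------------------------------------------------------------------ #
    # 9. survival chain and death-dependent numerators                    #
    # ------------------------------------------------------------------ #
    n_alive = n - m4n
    class_A = n - f2n
    class_B = f2n - f3n
    class_C = f3n - n_alive
    _check(class_A >= 0 and class_B >= 0 and class_C >= 0,
           "survival chain (M4 and F1 denominators must be nested)")
    if n_alive != f4n:
        notes["deviations"].append(
            f"F1 year-4 denominator: target {f4n} is unreachable given the survival chain; realized {n_alive}"
        )
    _check(f4k <= n_alive, "F1 year-4 numerator vs patients alive after 4 years")

    s1_fail_idx = df.index[df["s1_fail"]].tolist()
    df.loc[s1_fail_idx, "death_class"] = "A"
    death_pool = _Pool([i for i in df.index if not df.at[i, "s1_fail"]])
    # follow-up numerator members must live through the corresponding year
    df.loc[death_pool.take(class_A - len(s1_fail_idx), "deaths before year 2", rng), "death_class"] = "A"
    df.loc[death_pool.take(class_B, "deaths in year 2-3", rng), "death_class"] = "B"
    df.loc[death_pool.take(class_C, "deaths in year 3-4", rng), "death_class"] = "C"
    # remaining rows: alive at censoring (death_class None)

    dead_idx = df.index[df["death_class"].notna()].tolist()
    df.loc[_Pool(dead_idx).take(m4k, "M4 numerator among deceased patients", rng, logw), "m4num"] = True

    alive2 = df.index[df["death_class"].isin(["B", "C"]) | df["death_class"].isna()].tolist()
    alive3 = df.index[(df["death_class"] == "C") | df["death_class"].isna()].tolist()
    alive4 = df.index[df["death_class"].isna()].tolist()
    df.loc[_Pool(alive2).take(f2k, "F1 year-2 numerator", rng, logw), "f1y2"] = True
    df.loc[_Pool(alive3).take(f3k, "F1 year-3 numerator", rng, logw), "f1y3"] = True
    df.loc[_Pool(alive4).take(f4k, "F1 year-4 numerator", rng, logw), "f1y4"] = True

    # ------------------------------------------------------------------ #
    # 10. sparse codes: MDT evaluations and palliative admissions only    #
    #     ever appear at two providers (drives the feasibility audit)     #
    # ------------------------------------------------------------------ #
    o1_members = df.index[treated_mask & (df["o1"] != "out")].tolist()
    n_mdt = min(len(o1_members), max(2, n // 100))
    df.loc[_Pool(o1_members).take(n_mdt, "MDT evaluation recipients", rng), "mdt"] = True
    pall_pool = _Pool(df.index[(df["treatment"] == "none") & df["death_class"].notna()].tolist())
    n_pall = min(len(pall_pool.indices), max(2, n // 80))
    df.loc[pall_pool.take(n_pall, "palliative admissions", rng), "palliative"] = True
    bg_pool = _Pool(df.index[(df["treatment"] == "none") & df["death_class"].notna() & ~df["palliative"]].tolist())
    df.loc[bg_pool.take(len(bg_pool.indices) // 3, "background emergency accesses", rng), "emergency_bg"] = True

    # ------------------------------------------------------------------ #
    # 11. independent demographics and comorbidity classes                #
    # ------------------------------------------------------------------ #
    n_male = round(spec.male_frac * n)
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sexes)
    df["sex"] = sexes

    year_labels = sorted(spec.year_counts)
    year_quota = largest_remainder([spec.year_counts[y] for y in year_labels], n)
    years = np.concatenate([np.full(q, y) for y, q in zip(year_labels, year_quota)])
    rng.shuffle(years)
    df["year"] = years.astype(int)
    year_start = {y: to_day(f"{y}-01-01") for y in year_labels}
    days_in_year = {y: (to_day(f"{y}-12-31") - to_day(f"{y}-01-01")) for y in year_labels}
    df["inc"] = [year_start[y] + int(rng.integers(0, days_in_year[y] + 1)) for y in df["year"]]

    age_labels = list(spec.age_class_counts)
    age_quota = largest_remainder([spec.age_class_counts[a] for a in age_labels], n)
    age_ranges = {"<=55": (45, 55), "56-60": (56, 60), "61-65": (61, 65), "66-70": (66, 70),
                  "71-75": (71, 75), "76-80": (76, 80), ">80": (81, 92)}
    ages = np.concatenate([
        rng.integers(age_ranges[a][0], age_ranges[a][1] + 1, size=q)
        for a, q in zip(age_labels, age_quota)
    ])
    rng.shuffle(ages)
    df["age"] = ages.astype(int)

    ch_labels = ("0", "1", "2", ">=3")
    ch_quota = largest_remainder([spec.charlson_probs[c] for c in ch_labels], n)
    chs = np.concatenate([np.full(q, c) for c, q in zip(ch_labels, ch_quota)])
    rng.shuffle(chs)
    df["charlson4"] = chs

    # confirmation and morphology: SCLC always confirmed (8041); confirmed
    # NSCLC get adenocarcinoma codes; the rest are unconfirmed
    df["confirmed"] = False
    df["morphology"] = np.nan
    sclc_idx = df.index[df["histology"] == "SCLC"]
    df.loc[sclc_idx, "confirmed"] = True
    df.loc[sclc_idx, "morphology"] = 8041
    nsclc_conf = _Pool(df.index[df["histology"] == "NSCLC"].tolist()).take(
        confirmed_total - len(sclc_idx), "confirmed NSCLC cases", rng
    )
    df.loc[nsclc_conf, "confirmed"] = True
    df.loc[nsclc_conf, "morphology"] = 8140

    # ------------------------------------------------------------------ #
    # 12. concrete death days                                             #
    # ------------------------------------------------------------------ #
    ft_lag = {"num": 30, "den": 60, "out": 180}
    deaths = []
    for i in df.index:
        cls = df.at[i, "death_class"]
        if cls is None:
            deaths.append(None)
            continue
        inc = int(df.at[i, "inc"])
        treated = df.at[i, "treatment"] != "none"
        ft = inc + ft_lag[df.at[i, "o1"]] if treated else None
        if df.at[i, "s1_fail"]:
            deaths.append(ft + 15)
            continue
        margin = inc + 45  # clears every post-incidence diagnostic placement
        if treated:
            margin = max(margin, ft + 40)
            if df.at[i, "late_rt"]:
                margin = max(margin, ft + 121)
            if df.at[i, "post_crt"]:
                margin = max(margin, ft + 61)
            if df.at[i, "treatment"] == "surgery":
                margin = max(margin, ft + 45)  # covers discharge, re-access, post-op CT
        lo, hi = {"A": (margin, inc + 729), "B": (inc + 731, inc + 1094), "C": (inc + 1096, inc + 1459)}[cls]
        _check(lo <= hi, "death-day window vs scheduled events")
        deaths.append(int(rng.integers(lo, hi + 1)))
    df["death"] = deaths

    df["patient_id"] = [f"PT{i + 1:06d}" for i in range(len(df))]
    notes["realized"] = {
        "core": n,
        "f1y4_denominator": n_alive,
        "surgery": surg_total,
        "sclc": sclc_total,
    }
    notes["provider_effects"] = dict(zip(prov_ids, effects.tolist()))
    return df, notes
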