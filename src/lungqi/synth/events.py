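"""Event placement for one allocated patient profile.

Placement is entirely rule-based: every event day is chosen inside the
window that gives the patient exactly the indicator memberships their
profile flags prescribe, and outside every window that would add an
unintended membership.  The key discipline is the contact ladder for
treated patients, driven by the first-contact-to-first-therapy indicator:

* ``o1 == 'num'``   — therapy 30 days after incidence; every pre-therapy
  event lies within 60 days of the therapy date;
* ``o1 == 'den'``   — therapy 60 days after incidence; an anchor contact
  90 days before therapy fixes the interval above 60 days;
* ``o1 == 'out'``   — therapy at the 180-day ascertainment boundary and
  every other event strictly before incidence, so no contact falls in the
  180-day pre-therapy window.

Comorbidity codes sit 15-25 days before incidence, which is inside the
Charlson lookback for every profile and inside/outside the contact window
exactly as each profile requires.
"""

from __future__ import annotations

import math


def _lag(o1: str | None) -> int | None:
    return {"num": 30, "den": 60, "out": 180}.get(o1)


def plan_events(r, sparse_provider: str) -> list[tuple]:
    """Events for one profile row as ``(table, day, code, provider, discharge)``.

    ``r`` is a profile row (attribute access); ``sparse_provider`` is the
    provider at which rarely-coded procedures (MDT evaluations, palliative
    admissions) are billed, so that the feasibility audit sees them
    concentrated at a handful of providers.
    """
    ev: list[tuple] = []
    inc = int(r.inc)
    home = r.provider
    treated = r.treatment != "none"
    L = _lag(r.o1) if treated else None
    ft = inc + L if treated else None
    death = None if r.death is None or (isinstance(r.death, float) and math.isnan(r.death)) else int(r.death)

    def add(table, day, code, provider=None, discharge=None):
        ev.append((table, int(day), code, provider or home, discharge))

    # comorbidity history (Charlson lookback)
    if r.charlson4 == "1":
        add("outpatient", inc - 15, "CM_DIABETES")
    elif r.charlson4 == "2":
        add("inpatient", inc - 15, "CM_RENAL", discharge=inc - 14)
    elif r.charlson4 == ">=3":
        add("inpatient", inc - 15, "CM_RENAL", discharge=inc - 14)
        add("outpatient", inc - 25, "CM_DIABETES")

    # contact ladder
    if treated and r.o1 == "num":
        add("outpatient", ft - 30, "GP_VISIT")
    elif treated and r.o1 == "den":
        add("outpatient", ft - 90, "GP_VISIT")

    # therapy
    ct_lag = None if r.ct_lag is None or (isinstance(r.ct_lag, float) and math.isnan(r.ct_lag)) else int(r.ct_lag)
    pet_lag = None if r.pet_lag is None or (isinstance(r.pet_lag, float) and math.isnan(r.pet_lag)) else int(r.pet_lag)
    if r.treatment == "surgery":
        stay = 21 if r.s7 == "long" else 7
        add("inpatient", ft, r.surgery_type, discharge=ft + stay)
        if r.s6_fail:
            add("inpatient", ft + 20, "WEDGE_RESECTION", discharge=ft + 25)
        if r.s7 == "readmit":
            add("emergency", ft + stay + 10, "EMERGENCY_ACCESS")
        if ct_lag is not None:
            add("outpatient", ft - ct_lag, "CT_THORAX")
        if pet_lag is not None:
            add("outpatient", ft - pet_lag, "PET")
        if r.post_crt:
            add("outpatient", ft + 30, "CHEMO")
            add("outpatient", ft + 60, "RT_FRACTION")
    elif r.treatment == "chemoradiation":
        add("outpatient", ft, "CHEMO")
        add("outpatient", ft + 30, "RT_FRACTION")
    elif r.treatment == "chemotherapy":
        add("outpatient", ft, "CHEMO")
        if r.late_rt:
            add("outpatient", ft + 120, "RT_FRACTION")
    elif r.treatment == "radiotherapy":
        add("outpatient", ft, "RT_FRACTION")

    # pre-therapy imaging for medical patients
    if r.d3num and r.treatment != "surgery":
        add("outpatient", ft - 40, "PET")
    if r.d5num:
        add("outpatient", ft - 15, "CT_HEAD")
        add("outpatient", ft - 20, "BONE_SCAN")

    # SCLC staging work-up (always completed before incidence)
    if r.d6num:
        add("outpatient", inc - 5, "CT_THORAX")
        add("outpatient", inc - 10, "CT_ABDOMEN")
        add("outpatient", inc - 15, "CT_HEAD")
        add("outpatient", inc - 20, "BONE_SCAN")

    # biopsy pathway
    if r.d2_den:
        if not treated:
            biopsy, ct = inc + 10, inc - 10
        elif r.o1 == "num":
            biopsy, ct = ft - 20, ft - 40
        elif r.o1 == "den":
            biopsy, ct = ft - 35, ft - 50
        else:
            biopsy, ct = inc - 20, inc - 40
        if r.d6num and not r.d2_num and r.o1 != "out":
            biopsy = inc + 30  # keep the work-up CT out of the pre-biopsy window
        add("outpatient", biopsy, "BRONCHOSCOPY")
        if r.d2_num:
            add("outpatient", ct, "CT_THORAX")

    # standalone diagnostic CT where no other mechanism provides one
    if r.d1 and r.treatment != "surgery" and not r.d2_num and not r.d6num:
        if r.d2_den:  # biopsy present: keep the CT out of its 30-day window
            day = {"num": ft - 5 if ft else None, "den": ft - 25 if ft else None}.get(r.o1)
            if day is None:
                day = inc - 55 if r.o1 == "out" else inc + 41
        else:
            day = {"num": inc + 5, "den": inc + 10, "out": inc - 50}.get(r.o1, inc + 10)
        add("outpatient", day, "CT_THORAX")

    # sparsely-coded procedures, concentrated at dedicated providers
    if r.mdt:
        add("outpatient", ft - 10, "MDT_EVAL", provider=sparse_provider)
    if r.palliative and death is not None:
        add("inpatient", death - 30, "PALLIATIVE_CARE", provider=sparse_provider, discharge=death - 25)

    # end-of-life opioid prescription
    if r.m4num and death is not None:
        day = max(death - 30, ft + 1) if treated else death - 30
        add("prescriptions", day, "OPIOID_ATC")

    # follow-up visits
    for year, flag in ((2, r.f1y2), (3, r.f1y3), (4, r.f1y4)):
        if flag:
            add("outpatient", inc + 365 * (year - 1) + 180, "FOLLOWUP_VISIT")

    if r.emergency_bg and death is not None:
        add("emergency", death - 5, "EMERGENCY_ACCESS")

    if death is not None:
        bad = [e for e in ev if e[1] > death]
        if bad:  # guarded by the allocator's death-day margins
            raise AssertionError(f"event after death for {r.patient_id}: {bad}")
    return ev
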