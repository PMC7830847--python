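"""Cohort construction: exclusions, histology classification, Charlson
scoring, first-therapy assignment and provider attribution."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungqi.cohort import (
    assign_first_therapy,
    build_cohort,
    charlson_index,
    classify_histology,
)
from lungqi.errors import DuplicatePatientError
from lungqi.indicators.model import Event, to_day

from conftest import CENSOR, cohort_from_tables, make_tables


class TestBuildCohort:
    def test_hand_counted_exclusions(self):
        patients = (
            [{"patient_id": f"K{i}"} for i in range(7)]
            + [{"patient_id": "D1x", "dco": True}, {"patient_id": "D2x", "dco": True}]
            + [{"patient_id": "M1x", "morphology": 8800}]
        )
        retained, log = build_cohort(make_tables(patients, [])["registry"])
        assert len(retained) == 7
        assert log == {"input": 10, "excluded_dco": 2, "excluded_mesenchymal": 1, "retained": 7}

    def test_no_flags_is_identity(self):
        reg = make_tables([{"patient_id": f"K{i}"} for i in range(5)], [])["registry"]
        retained, log = build_cohort(reg)
        assert len(retained) == 5 and log["excluded_dco"] == 0

    def test_conservation(self, milan_data):
        retained, log = build_cohort(milan_data.registry)
        assert log["retained"] + log["excluded_dco"] + log["excluded_mesenchymal"] == log["input"]
        assert len(retained) == log["retained"]

    def test_duplicate_ids_rejected_with_listing(self):
        reg = make_tables(
            [{"patient_id": "A"}, {"patient_id": "A"}, {"patient_id": "B"}], []
        )["registry"]
        with pytest.raises(DuplicatePatientError) as err:
            build_cohort(reg)
        assert err.value.duplicates == ["A"]


@pytest.mark.parametrize(
    "morphology, confirmed, expected",
    [
        (8041, True, "SCLC"),
        (8045, True, "SCLC"),
        (8040, True, "NSCLC"),
        (8046, True, "NSCLC"),
        (8140, True, "NSCLC"),   # adenocarcinoma
        (None, False, "NSCLC"),  # not cyto-histologically confirmed
        (None, True, "NSCLC"),
        (8041, False, "NSCLC"),
    ],
)
def test_histology_classification(morphology, confirmed, expected):
    assert classify_histology(morphology, confirmed) == expected


def test_histology_partitions_cohort(milan_cohort):
    counts = milan_cohort["histology"].value_counts()
    assert counts.get("NSCLC", 0) + counts.get("SCLC", 0) == len(milan_cohort)


class TestCharlson:
    INC = "2010-06-01"

    def _ev(self, code, days_before, table="outpatient"):
        return Event(to_day(self.INC) - days_before, code, table, "P001")

    def test_no_comorbidities(self):
        score, cls3, cls4 = charlson_index(self.INC, [])
        assert (score, cls3, cls4) == (0, "0", "0")

    def test_weight_sum_and_class(self):
        events = [self._ev("CM_DIABETES", 30), self._ev("CM_RENAL", 60, "inpatient")]
        score, cls3, cls4 = charlson_index(self.INC, events)
        assert score == 3 and cls3 == ">=3" and cls4 == ">=3"

    def test_distinct_conditions_counted_once(self):
        events = [self._ev("CM_DIABETES", 30), self._ev("CM_DIABETES", 90)]
        assert charlson_index(self.INC, events)[0] == 1

    def test_lookback_window_boundaries(self):
        assert charlson_index(self.INC, [self._ev("CM_DIABETES", 365)])[0] == 1
        assert charlson_index(self.INC, [self._ev("CM_DIABETES", 366)])[0] == 0
        assert charlson_index(self.INC, [self._ev("CM_DIABETES", 0)])[0] == 0  # on incidence day

    def test_prescription_codes_ignored(self):
        assert charlson_index(self.INC, [self._ev("CM_DIABETES", 30, "prescriptions")])[0] == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from(["CM_MI", "CM_COPD", "CM_RENAL", "CM_LIVER_SEVERE"]),
                    max_size=6),
           st.sampled_from(["CM_DIABETES", "CM_AIDS"]))
    def test_monotone_under_added_comorbidity(self, codes, extra):
        base = [self._ev(c, 30 + 5 * i) for i, c in enumerate(codes)]
        s0 = charlson_index(self.INC, base)[0]
        s1 = charlson_index(self.INC, base + [self._ev(extra, 100)])[0]
        assert s1 >= s0

    def test_cohort_class_zero_fraction_matches_spec(self, milan_cohort, milan_spec):
        frac0 = (milan_cohort["charlson_class4"] == "0").mean()
        assert abs(frac0 - milan_spec.charlson_probs["0"]) < 0.02


class TestFirstTherapy:
    INC = "2010-06-01"

    def _ev(self, code, day_offset, table="outpatient"):
        return Event(to_day(self.INC) + day_offset, code, table, "P001")

    def test_earliest_event_wins(self):
        events = [self._ev("LOBECTOMY", 20, "inpatient"), self._ev("CHEMO", 60)]
        kind, date = assign_first_therapy(self.INC, events)
        assert kind == "surgery" and to_day(date) == to_day(self.INC) + 20

    def test_chemo_and_radio_within_gap_is_chemoradiation(self):
        events = [self._ev("CHEMO", 30), self._ev("RT_FRACTION", 45)]
        kind, date = assign_first_therapy(self.INC, events)
        assert kind == "chemoradiation" and to_day(date) == to_day(self.INC) + 30

    def test_gap_beyond_90_days_stays_chemotherapy(self):
        events = [self._ev("CHEMO", 30), self._ev("RT_FRACTION", 121)]
        assert assign_first_therapy(self.INC, events)[0] == "chemotherapy"

    def test_no_treatment_events(self):
        assert assign_first_therapy(self.INC, [self._ev("CT_THORAX", 10)]) == ("none", None)

    def test_ascertainment_window_boundary(self):
        assert assign_first_therapy(self.INC, [self._ev("CHEMO", 180)])[0] == "chemotherapy"
        assert assign_first_therapy(self.INC, [self._ev("CHEMO", 181)])[0] == "none"
        assert assign_first_therapy(self.INC, [self._ev("CHEMO", -5)])[0] == "none"

    def test_cohort_treatment_mix_matches_spec(self, milan_cohort, milan_spec):
        counts = milan_cohort["first_therapy"].value_counts().to_dict()
        assert counts == milan_spec.treatment_counts


class TestAttribution:
    def _surgical(self, events):
        tables = make_tables([{"patient_id": "A", "stage": "I"}], events)
        cohort, ev = cohort_from_tables(tables)
        return cohort, ev

    def test_earliest_relevant_event_provider(self, catalog):
        from lungqi.indicators.engine import evaluate
        cohort, ev = self._surgical(
            [
                {"patient_id": "A", "table": "inpatient", "date": "2010-07-01",
                 "code": "LOBECTOMY", "discharge_date": "2010-07-08", "provider_id": "P009"},
                {"patient_id": "A", "table": "inpatient", "date": "2010-08-01",
                 "code": "WEDGE_RESECTION", "discharge_date": "2010-08-05", "provider_id": "P001"},
            ]
        )
        res = evaluate(catalog["S1"], cohort, ev, CENSOR, catalog)
        assert list(res.providers["provider_id"]) == ["P009"]

    def test_same_day_tie_breaks_to_lowest_provider_id(self, catalog):
        from lungqi.indicators.engine import evaluate
        cohort, ev = self._surgical(
            [
                {"patient_id": "A", "table": "inpatient", "date": "2010-07-01",
                 "code": "LOBECTOMY", "discharge_date": "2010-07-08", "provider_id": "P030"},
                {"patient_id": "A", "table": "inpatient", "date": "2010-07-01",
                 "code": "PNEUMONECTOMY", "discharge_date": "2010-07-09", "provider_id": "P007"},
            ]
        )
        res = evaluate(catalog["S1"], cohort, ev, CENSOR, catalog)
        assert list(res.providers["provider_id"]) == ["P007"]

    def test_no_relevant_event_excluded_from_provider_analysis(self, catalog):
        from lungqi.indicators.engine import evaluate
        tables = make_tables([{"patient_id": "A", "stage": "I", "death_date": "2012-01-01"}], [])
        cohort, ev = cohort_from_tables(tables)
        res = evaluate(catalog["M4"], cohort, ev, CENSOR, catalog)
        assert res.denominator == 1 and len(res.providers) == 0

    def test_attribution_stable_under_event_order_permutation(self, catalog, rng):
        from lungqi.indicators.engine import evaluate
        events = [
            {"patient_id": "A", "table": "inpatient", "date": "2010-07-01",
             "code": "LOBECTOMY", "discharge_date": "2010-07-08", "provider_id": "P030"},
            {"patient_id": "A", "table": "outpatient", "date": "2010-06-20",
             "code": "CT_THORAX", "provider_id": "P011"},
            {"patient_id": "A", "table": "outpatient", "date": "2010-06-01",
             "code": "GP_VISIT", "provider_id": "P002"},
        ]
        seen = set()
        for _ in range(4):
            rng.shuffle(events)
            cohort, ev = cohort_from_tables(make_tables([{"patient_id": "A", "stage": "I"}], events))
            res = evaluate(catalog["O1"], cohort, ev, CENSOR, catalog)
            seen.update(res.providers["provider_id"])
        assert seen == {"P002"}
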