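"""Index dates, continuous-enrollment arithmetic and cohort eligibility."""

import pandas as pd
import pytest

from haeclaims.cohort import (
    BACKWARD,
    FORWARD,
    build_cohorts,
    continuous_enrollment_days,
    find_index_date,
    merge_spans,
)
from haeclaims.fixtures import _Builder
from haeclaims.schema import empty_dataset

IDX = pd.Timestamp("2010-06-01")


def _pharm(rows):
    return pd.DataFrame(rows, columns=["patient_id", "fill_date", "product",
                                       "quantity_iu", "days_supply"])


def _spans(pairs, pid="p1"):
    return pd.DataFrame(
        [{"patient_id": pid, "span_start": pd.Timestamp(s), "span_end": pd.Timestamp(e)}
         for s, e in pairs])


class TestIndexDate:
    def test_androgen_fills_are_not_index_eligible(self):
        pharm = _pharm([("p1", pd.Timestamp("2010-01-01"), "ANDROGEN", None, 30),
                        ("p1", pd.Timestamp("2010-06-01"), "ICATIBANT", None, None)])
        assert find_index_date(pharm) == pd.Timestamp("2010-06-01")

    def test_no_claims_returns_none(self):
        assert find_index_date(_pharm([])) is None

    def test_same_day_tie_returns_that_day(self):
        pharm = _pharm([("p1", IDX, "CINRYZE", 1500.0, 7),
                        ("p1", IDX, "ICATIBANT", None, None)])
        assert find_index_date(pharm) == IDX


def enumeration_oracle(pairs, anchor, direction, grace):
    """Oracle: bridge short gaps day-by-day, then walk outward from anchor."""
    covered = set()
    for s, e in pairs:
        d = pd.Timestamp(s)
        while d <= pd.Timestamp(e):
            covered.add(d)
            d += pd.Timedelta(days=1)
    # an uncovered run of <= grace days strictly between covered days is bridged
    day_list = sorted(covered)
    effective = set(covered)
    for a, b in zip(day_list, day_list[1:]):
        gap = (b - a).days - 1
        if 0 < gap <= grace:
            d = a + pd.Timedelta(days=1)
            while d < b:
                effective.add(d)
                d += pd.Timedelta(days=1)
    step = pd.Timedelta(days=1) if direction == FORWARD else -pd.Timedelta(days=1)
    day, n = pd.Timestamp(anchor), 0
    if day not in effective:
        return 0
    while day + step in effective:
        day, n = day + step, n + 1
    return n


class TestContinuousEnrollment:
    def test_single_span_forward(self):
        spans = _spans([(IDX - pd.Timedelta(days=200), IDX + pd.Timedelta(days=400))])
        assert continuous_enrollment_days(spans, IDX, FORWARD) == 400
        assert continuous_enrollment_days(spans, IDX, BACKWARD) == 200

    def test_gap_breaks_continuity_at_grace_zero(self):
        spans = _spans([(IDX - pd.Timedelta(days=100), IDX + pd.Timedelta(days=10)),
                        (IDX + pd.Timedelta(days=12), IDX + pd.Timedelta(days=300))])
        assert continuous_enrollment_days(spans, IDX, FORWARD, grace_days=0) == 10

    def test_grace_bridges_small_gap(self):
        spans = _spans([(IDX - pd.Timedelta(days=100), IDX + pd.Timedelta(days=10)),
                        (IDX + pd.Timedelta(days=12), IDX + pd.Timedelta(days=300))])
        assert continuous_enrollment_days(spans, IDX, FORWARD, grace_days=7) == 300

    def test_malformed_span_raises(self):
        spans = _spans([(IDX, IDX - pd.Timedelta(days=1))])
        with pytest.raises(ValueError, match="malformed"):
            continuous_enrollment_days(spans, IDX)

    @pytest.mark.parametrize("grace", [0, 1, 7, 30])
    @pytest.mark.parametrize("direction", [FORWARD, BACKWARD])
    def test_matches_day_enumeration_oracle(self, grace, direction):
        import numpy as np
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_spans = rng.integers(1, 4)
            pairs, cursor = [], IDX - pd.Timedelta(days=int(rng.integers(0, 60)))
            for _ in range(n_spans):
                length = int(rng.integers(0, 80))
                pairs.append((cursor, cursor + pd.Timedelta(days=length)))
                cursor += pd.Timedelta(days=length + int(rng.integers(1, 40)))
            got = continuous_enrollment_days(_spans(pairs), IDX, direction, grace)
            assert got == enumeration_oracle(pairs, IDX, direction, grace)

    def test_adjacent_spans_merge(self):
        a, b = IDX - pd.Timedelta(days=10), IDX + pd.Timedelta(days=5)
        spans = _spans([(a, b), (b + pd.Timedelta(days=1), IDX + pd.Timedelta(days=90))])
        assert merge_spans(spans) == [(a, IDX + pd.Timedelta(days=90))]


def _one_patient_dataset(pre_days, post_days, with_dx=True, product="ICATIBANT"):
    b = _Builder()
    b.patient("p1")
    b.enroll("p1", IDX - pd.Timedelta(days=pre_days), IDX + pd.Timedelta(days=post_days))
    if with_dx:
        b.med("p1", IDX, "OFFICE", dx1="277.6")
    b.fill("p1", IDX, product, iu=None, supply=None)
    return b.build()


class TestBuildCohorts:
    def test_overall_without_hcru(self):
        ds = _one_patient_dataset(pre_days=30, post_days=120)
        cohort, _ = build_cohorts(ds)
        rec = cohort.iloc[0]
        assert rec["in_overall"] and not rec["in_hcru"]
        assert rec["pre_enroll_days"] == 30 and rec["post_enroll_days"] == 120

    def test_missing_diagnosis_excludes(self):
        ds = _one_patient_dataset(200, 200, with_dx=False)
        cohort, attrition = build_cohorts(ds)
        assert not cohort.iloc[0]["in_overall"]
        att = attrition.set_index("criterion")["n_patients"]
        assert att["no_hae_diagnosis"] == 1

    def test_short_post_enrollment_excludes(self):
        ds = _one_patient_dataset(200, 60)
        cohort, attrition = build_cohorts(ds)
        assert not cohort.iloc[0]["in_overall"]
        att = attrition.set_index("criterion")["n_patients"]
        assert att["insufficient_post_enrollment"] == 1

    def test_empty_dataset_gives_empty_cohort(self):
        cohort, attrition = build_cohorts(empty_dataset())
        assert len(cohort) == 0
        assert attrition["n_patients"].sum() == 0

    def test_hcru_subset_of_overall_and_attrition_sums(self, sim_small):
        cohort, attrition = build_cohorts(sim_small)
        assert (cohort["in_hcru"] <= cohort["in_overall"]).all()
        pharm = sim_small.pharmacy
        n_candidates = pharm.loc[pharm["product"].isin(
            ["CINRYZE", "BERINERT", "ICATIBANT", "ECALLANTIDE"]),
            "patient_id"].nunique()
        assert attrition["n_patients"].sum() == n_candidates == len(cohort)

    def test_date_shift_invariance(self, sim_small):
        shift = pd.Timedelta(days=37)
        shifted = type(sim_small)(
            patients=sim_small.patients,
            enrollment=sim_small.enrollment.assign(
                span_start=sim_small.enrollment["span_start"] + shift,
                span_end=sim_small.enrollment["span_end"] + shift),
            pharmacy=sim_small.pharmacy.assign(
                fill_date=sim_small.pharmacy["fill_date"] + shift),
            medical=sim_small.medical.assign(
                service_date=sim_small.medical["service_date"] + shift),
        )
        c1, _ = build_cohorts(sim_small)
        c2, _ = build_cohorts(shifted)
        assert ((c2["index_date"] - c1["index_date"]) == shift).all()
        for col in ("in_overall", "in_hcru", "pre_enroll_days", "post_enroll_days"):
            assert (c1[col] == c2[col]).all()
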