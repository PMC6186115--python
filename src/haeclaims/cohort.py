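"""Cohort construction: medication index date, enrollment windows, eligibility.

Overall cohort: a recorded HAE diagnosis (ICD-9-CM 277.6 on any claim during
the study period), at least one fill of an HAE-specific medication (the two
C1-INH(IV) brands, icatibant, or ecallantide — patients on oral androgens or
tranexamic acid alone are not index-eligible), and at least 3 months (90
days) of continuous enrollment after the index date.  The HCRU analysis
cohort additionally requires 90 days of continuous enrollment before the
index date and 30 days after.  Months are fixed at 30 days; calendar-month
arithmetic is ambiguous across month lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .schema import ClaimsDataset, HAE_SPECIFIC_PRODUCTS, medical_has_dx

logger = logging.getLogger(__name__)

FORWARD = "forward"
BACKWARD = "backward"


@dataclass(frozen=True)
class CohortConfig:
    """Eligibility windows (days) and enrollment gap tolerance."""

    month_days: int = 30
    min_post_index_months_overall: int = 3
    min_pre_index_months_hcru: int = 3
    min_post_index_months_hcru: int = 1
    grace_days: int = 0  # enrollment gaps up to this many days are bridged

    @property
    def post_days_overall(self) -> int:
        return self.min_post_index_months_overall * self.month_days

    @property
    def pre_days_hcru(self) -> int:
        return self.min_pre_index_months_hcru * self.month_days

    @property
    def post_days_hcru(self) -> int:
        return self.min_post_index_months_hcru * self.month_days


DEFAULT_CONFIG = CohortConfig()


def find_index_date(pharmacy: pd.DataFrame):
    """Earliest HAE-specific fill date for one patient's claims, or None.

    Androgen/tranexamic-acid fills never set the index date.
    """
    eligible = pharmacy[pharmacy["product"].isin(HAE_SPECIFIC_PRODUCTS)]
    if eligible.empty:
        return None
    return pd.Timestamp(eligible["fill_date"].min())


def merge_spans(spans: pd.DataFrame, grace_days: int = 0) -> list[tuple]:
    """Normalize enrollment spans: sort and bridge gaps of <= grace_days.

    A gap is the count of uncovered days between two spans, so adjacent
    spans (end + 1 day = next start) merge even at grace 0.
    """
    if (spans["span_end"] < spans["span_start"]).any():
        raise ValueError("malformed enrollment span: end < start")
    intervals = sorted(
        (pd.Timestamp(s), pd.Timestamp(e))
        for s, e in zip(spans["span_start"], spans["span_end"]))
    merged: list[list] = []
    for s, e in intervals:
        if merged and (s - merged[-1][1]).days - 1 <= grace_days:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def continuous_enrollment_days(spans: pd.DataFrame, anchor,
                               direction: str = FORWARD,
                               grace_days: int = 0) -> int:
    """Days of unbroken coverage from `anchor` in the given direction.

    Returns 0 when the anchor date is not covered by any (merged) span.
    """
    anchor = pd.Timestamp(anchor)
    for start, end in merge_spans(spans, grace_days):
        if start <= anchor <= end:
            if direction == FORWARD:
                return (end - anchor).days
            if direction == BACKWARD:
                return (anchor - start).days
            raise ValueError(f"unknown direction {direction!r}")
    return 0


def enrollment_end_after(spans: pd.DataFrame, anchor, grace_days: int = 0):
    """End date of the merged enrollment period covering `anchor`, or None."""
    anchor = pd.Timestamp(anchor)
    for start, end in merge_spans(spans, grace_days):
        if start <= anchor <= end:
            return end
    return None


def build_cohorts(dataset: ClaimsDataset,
                  config: CohortConfig = DEFAULT_CONFIG):
    """Apply inclusion criteria to every patient with an HAE-specific fill.

    Returns ``(cohort, attrition)``: one CohortRecord row per patient holding
    an index date, and an attrition table whose exclusion counts plus the
    included count equal the number of distinct patients with any
    HAE-specific fill.  Patients are excluded by the first failing criterion
    in order: no HAE diagnosis claim, then insufficient post-index
    enrollment.
    """
    pharm = dataset.pharmacy
    med = dataset.medical
    if len(dataset.patients) == 0:
        logger.warning("empty dataset: returning empty cohort")
    candidates = sorted(
        pharm.loc[pharm["product"].isin(HAE_SPECIFIC_PRODUCTS), "patient_id"].unique())
    hae_dx_patients = set(med.loc[medical_has_dx(med), "patient_id"].unique())

    rows = []
    attrition = {"no_hae_diagnosis": 0, "insufficient_post_enrollment": 0,
                 "included_overall": 0}
    for pid in candidates:
        sub_pharm = pharm[pharm["patient_id"] == pid]
        index_date = find_index_date(sub_pharm)
        spans = dataset.enrollment[dataset.enrollment["patient_id"] == pid]
        post = continuous_enrollment_days(spans, index_date, FORWARD,
                                          config.grace_days) if len(spans) else 0
        pre = continuous_enrollment_days(spans, index_date, BACKWARD,
                                         config.grace_days) if len(spans) else 0
        has_dx = pid in hae_dx_patients
        in_overall = has_dx and post >= config.post_days_overall
        in_hcru = (in_overall and pre >= config.pre_days_hcru
                   and post >= config.post_days_hcru)
        if not has_dx:
            attrition["no_hae_diagnosis"] += 1
        elif not in_overall:
            attrition["insufficient_post_enrollment"] += 1
        else:
            attrition["included_overall"] += 1
        rows.append({
            "patient_id": pid,
            "index_date": index_date,
            "in_overall": in_overall,
            "in_hcru": in_hcru,
            "pre_enroll_days": pre,
            "post_enroll_days": post,
        })
    cohort = pd.DataFrame(rows, columns=[
        "patient_id", "index_date", "in_overall", "in_hcru",
        "pre_enroll_days", "post_enroll_days"])
    attrition_df = pd.DataFrame(
        [{"criterion": k, "n_patients": v} for k, v in attrition.items()])
    logger.info("cohort built: %d candidates, %d overall, %d HCRU",
                len(candidates), int(cohort["in_overall"].sum()),
                int(cohort["in_hcru"].sum()))
    return cohort, attrition_df
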