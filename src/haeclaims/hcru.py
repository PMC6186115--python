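"""Healthcare resource utilization: hospitalizations, ED visits, office visits.

Counting conventions (standard for claim-line data):

* a hospitalization is a maximal run of consecutive inpatient claim days —
  claim-line granularity would otherwise inflate admission counts;
* an ED claim on the same day as an inpatient claim for the same patient is
  folded into the hospitalization (ED-to-admission pathway), counting no
  separate ED visit;
* office visits are distinct office-claim days.

Each setting is counted all-cause, HAE-related (the claim carries the HAE
diagnosis in any position) and CVAD-related (the claim carries a CVAD
procedure code).  Counts are produced both inside the 12-month post-index
follow-up window (truncated at enrollment end) and as any-use flags over
the full study period, which is what the crude stratified rate table uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import enrollment_end_after
from .cvad import cvad_procedure_codes
from .schema import ED, INPATIENT, OFFICE, OTHER, medical_has_dx, medical_has_proc

HOSPITALIZATION = "HOSPITALIZATION"

FOLLOW_UP_DAYS = 365


@dataclass(frozen=True)
class HcruConfig:
    follow_up_days: int = FOLLOW_UP_DAYS
    grace_days: int = 0


def classify_setting(claims: pd.DataFrame) -> pd.Series:
    """Map claim settings to counted categories, folding same-day ED+inpatient.

    Returns a Series aligned to ``claims`` with values in
    {HOSPITALIZATION, ED, OFFICE, OTHER}.
    """
    out = claims["setting"].map({
        INPATIENT: HOSPITALIZATION, ED: ED, OFFICE: OFFICE, OTHER: OTHER})
    inpatient_days = set(map(tuple, claims.loc[
        claims["setting"] == INPATIENT, ["patient_id", "service_date"]].itertuples(index=False)))
    fold = claims.apply(
        lambda r: r["setting"] == ED
        and (r["patient_id"], r["service_date"]) in inpatient_days, axis=1)
    if fold.any():
        out = out.mask(fold, HOSPITALIZATION)
    return out


def _count_admissions(days: np.ndarray) -> int:
    """Number of maximal runs of consecutive days (days: sorted unique)."""
    if len(days) == 0:
        return 0
    return 1 + int((np.diff(days) > 1).sum())


def _summarize_window(claims: pd.DataFrame, hae_mask, cvad_mask) -> dict:
    """Counts for one patient's claims (already filtered to a window)."""
    cat = classify_setting(claims) if len(claims) else pd.Series(dtype=object)

    def counts(mask) -> dict:
        sub = claims[mask] if len(claims) else claims
        subcat = cat[mask] if len(claims) else cat
        hosp_days = np.sort(sub.loc[subcat == HOSPITALIZATION, "service_date"]
                            .dt.normalize().unique()).astype("datetime64[D]").astype(int)
        ed_days = sub.loc[subcat == ED, "service_date"].dt.normalize().nunique()
        office_days = sub.loc[subcat == OFFICE, "service_date"].dt.normalize().nunique()
        return {
            "n_hospitalizations": _count_admissions(hosp_days),
            "n_ed_visits": int(ed_days),
            "n_office_visits": int(office_days),
        }
    all_cause = counts(pd.Series(True, index=claims.index))
    hae = counts(hae_mask)
    cvad = counts(cvad_mask)
    out = dict(all_cause)
    out.update({f"hae_{k}": v for k, v in hae.items()})
    out.update({f"cvad_{k}": v for k, v in cvad.items()})
    return out


def summarize_hcru(dataset, cohort: pd.DataFrame,
                   config: HcruConfig = HcruConfig()) -> pd.DataFrame:
    """Per-patient utilization for HCRU-eligible cohort members.

    Window counts cover [index, index + min(follow_up_days, enrollment end)];
    ``any_*_study`` flags cover the patient's full claim history.
    """
    med = dataset.medical
    hae_mask_all = medical_has_dx(med)
    cvad_mask_all = medical_has_proc(med, cvad_procedure_codes())
    rows = []
    eligible = cohort[cohort["in_hcru"]]
    for _, rec in eligible.iterrows():
        pid, index_date = rec["patient_id"], pd.Timestamp(rec["index_date"])
        spans = dataset.enrollment[dataset.enrollment["patient_id"] == pid]
        enroll_end = enrollment_end_after(spans, index_date, config.grace_days)
        window_end = index_date + pd.Timedelta(days=config.follow_up_days)
        if enroll_end is not None:
            window_end = min(window_end, enroll_end)
        mine = med["patient_id"] == pid
        in_window = mine & (med["service_date"] >= index_date) \
            & (med["service_date"] <= window_end)
        w = _summarize_window(med[in_window], hae_mask_all[in_window],
                              cvad_mask_all[in_window])
        s = _summarize_window(med[mine], hae_mask_all[mine], cvad_mask_all[mine])
        rows.append({
            "patient_id": pid,
            "follow_up_days": int((window_end - index_date).days),
            **w,
            "any_hosp": w["n_hospitalizations"] >= 1,
            "any_ed": w["n_ed_visits"] >= 1,
            "any_office": w["n_office_visits"] >= 1,
            "any_hosp_study": s["n_hospitalizations"] >= 1,
            "any_ed_study": s["n_ed_visits"] >= 1,
            "any_office_study": s["n_office_visits"] >= 1,
        })
    cols = ["patient_id", "follow_up_days",
            "n_hospitalizations", "n_ed_visits", "n_office_visits",
            "hae_n_hospitalizations", "hae_n_ed_visits", "hae_n_office_visits",
            "cvad_n_hospitalizations", "cvad_n_ed_visits", "cvad_n_office_visits",
            "any_hosp", "any_ed", "any_office",
            "any_hosp_study", "any_ed_study", "any_office_study"]
    return pd.DataFrame(rows, columns=cols)


def crude_rate_table(summaries: pd.DataFrame, c1inh_user: pd.Series,
                     cvad_user: pd.Series, period: str = "study") -> pd.DataFrame:
    """Crude any-hospitalization / any-ED rates stratified two ways.

    ``c1inh_user`` / ``cvad_user`` are boolean Series indexed by patient_id.
    Row percentages are numerator/denominator x 100, reported to 1 decimal.
    ``period`` selects the full-study flags ("study") or the follow-up
    window flags ("window").
    """
    hosp_col = "any_hosp_study" if period == "study" else "any_hosp"
    ed_col = "any_ed_study" if period == "study" else "any_ed"
    df = summaries.set_index("patient_id")
    c1 = c1inh_user.reindex(df.index).fillna(False).astype(bool)
    cv = cvad_user.reindex(df.index).fillna(False).astype(bool)

    def row(label, mask):
        n = int(mask.sum())
        nh = int(df.loc[mask, hosp_col].sum())
        ne = int(df.loc[mask, ed_col].sum())
        return {
            "stratum": label, "n": n,
            "n_hospitalization": nh,
            "pct_hospitalization": round(100.0 * nh / n, 1) if n else None,
            "n_ed_visit": ne,
            "pct_ed_visit": round(100.0 * ne / n, 1) if n else None,
        }
    everyone = pd.Series(True, index=df.index)
    return pd.DataFrame([
        row("overall", everyone),
        row("c1inh_iv_users", c1),
        row("non_c1inh_iv_users", ~c1),
        row("cvad_users", cv),
        row("non_cvad_users", ~cv),
    ])
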