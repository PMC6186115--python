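"""Central venous access devices: identification, relatedness, complications.

Subcutaneous ports for long-term intravenous infusion are identified from
procedure codes for insertion, repair, partial/complete replacement and
removal.  Because published claim analyses rarely print their exact CPT and
ICD-9-CM lists, this package ships *symbolic* codes (INSERT_PORT,
REMOVE_PORT, REPAIR_PORT, REPLACE_PART, REPLACE_FULL and catheter
complication diagnoses); a user-supplied mapping table (same layout as
``data/cvad_codes.csv``) translates real codes onto the symbolic set.

A device is deemed related to intravenous HAE-medication use under either
claim pattern:

A. inserted no more than 13 weeks (91 days) before the medication index
   date and still in place at least 30 days after it; or
B. inserted at any time during the use of an HAE-specific medication and in
   place for 30 days or longer.

A device without a removal claim is assumed in place through the end of the
patient's continuous enrollment: the absence of a claim is not evidence of
removal, and both patterns need an end bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

from .cohort import enrollment_end_after
from .episodes import DEFAULT_CONFIG as EPISODE_CONFIG, EpisodeConfig, segment_runs
from .schema import HAE_SPECIFIC_PRODUCTS, medical_has_proc, DX_COLUMNS

logger = logging.getLogger(__name__)

MECHANICAL = "MECHANICAL"
REPLACEMENT = "REPLACEMENT"
INFECTION_OTHER_UNSPEC = "INFECTION_OTHER_UNSPEC"
INFECTION_LOCAL = "INFECTION_LOCAL"
COMPLICATION_CATEGORIES = (
    MECHANICAL, REPLACEMENT, INFECTION_OTHER_UNSPEC, INFECTION_LOCAL)

PRE_INDEX_WINDOW_DAYS = 91   # 13 weeks
MIN_IN_PLACE_DAYS = 30
COMPLICATION_WINDOW_DAYS = 30  # grace past device end for complication claims


@lru_cache(maxsize=1)
def load_code_map() -> dict[str, dict[str, set[str]]]:
    """{'proc'|'dx' -> {role -> set of user codes}} from the shipped asset."""
    with resources.files("haeclaims.data").joinpath("cvad_codes.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    out: dict[str, dict[str, set[str]]] = {"proc": {}, "dx": {}}
    for _, row in df.iterrows():
        out[row["kind"]].setdefault(row["role"], set()).add(row["user_code"])
    return out


def _role_codes(kind: str, role: str) -> set[str]:
    return load_code_map()[kind].get(role, set())


def cvad_procedure_codes() -> set[str]:
    """All procedure codes that mark a claim as CVAD-related."""
    return set().union(*load_code_map()["proc"].values())


@dataclass
class ComplicationEvent:
    date: pd.Timestamp
    category: str


@dataclass
class CvadRecord:
    patient_id: object
    insertion_date: pd.Timestamp
    removal_date: pd.Timestamp | None
    in_place_end: pd.Timestamp
    related: bool | None = None
    complications: list = field(default_factory=list)

    @property
    def in_place_days(self) -> int:
        return (self.in_place_end - self.insertion_date).days


def identify_cvads(medical: pd.DataFrame, enrollment: pd.DataFrame,
                   grace_days: int = 0) -> list[CvadRecord]:
    """Pair insertion and removal procedure claims into device intervals.

    Each insertion opens a device; a removal closes the most recently
    opened device still open for that patient (removals with no open device
    are logged and ignored).  Open devices run to the end of the merged
    enrollment period containing the insertion.
    """
    insert_codes, remove_codes = _role_codes("proc", "insertion"), _role_codes("proc", "removal")
    events = []
    ins_mask = medical_has_proc(medical, insert_codes)
    rem_mask = medical_has_proc(medical, remove_codes)
    for _, row in medical[ins_mask | rem_mask].iterrows():
        kind = "insert" if ins_mask.loc[row.name] else "remove"
        events.append((row["patient_id"], pd.Timestamp(row["service_date"]), kind))

    devices: list[CvadRecord] = []
    by_patient: dict = {}
    for pid, date, kind in sorted(events, key=lambda e: (str(e[0]), e[1], e[2])):
        by_patient.setdefault(pid, []).append((date, kind))
    for pid, evs in by_patient.items():
        spans = enrollment[enrollment["patient_id"] == pid]
        open_stack: list[CvadRecord] = []
        for date, kind in evs:
            if kind == "insert":
                end = enrollment_end_after(spans, date, grace_days) if len(spans) else None
                rec = CvadRecord(pid, date, None, end if end is not None else date)
                open_stack.append(rec)
                devices.append(rec)
            else:
                if not open_stack:
                    logger.warning("removal with no open CVAD for patient %s on %s",
                                   pid, date.date())
                    continue
                rec = open_stack.pop()
                rec.removal_date = date
                rec.in_place_end = date
    return devices


def medication_use_intervals(pharmacy: pd.DataFrame,
                             config: EpisodeConfig = EPISODE_CONFIG) -> list[tuple]:
    """Union of HAE-specific refill runs (any product), with terminal coverage.

    These intervals bound "during the use of an HAE-specific medication"
    for relatedness pattern B.
    """
    intervals = []
    sub = pharmacy[pharmacy["product"].isin(HAE_SPECIFIC_PRODUCTS)]
    for (pid, product), grp in sub.groupby(["patient_id", "product"]):
        fills = [(pid, product, r["fill_date"], 0.0 if pd.isna(r["quantity_iu"])
                  else r["quantity_iu"], r["days_supply"])
                 for _, r in grp.iterrows()]
        for run in segment_runs(fills, config):
            intervals.append((run.start_date, run.end_date))
    intervals.sort()
    merged: list[list] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def is_related(device: CvadRecord, index_date, use_intervals) -> bool:
    """Apply relatedness patterns A and B (see module docstring)."""
    index_date = pd.Timestamp(index_date)
    pattern_a = (
        index_date - pd.Timedelta(days=PRE_INDEX_WINDOW_DAYS)
        <= device.insertion_date <= index_date
        and device.in_place_end >= index_date + pd.Timedelta(days=MIN_IN_PLACE_DAYS))
    pattern_b = any(
        s <= device.insertion_date <= e for s, e in use_intervals
    ) and device.in_place_days >= MIN_IN_PLACE_DAYS
    return bool(pattern_a or pattern_b)


def classify_complications(device: CvadRecord, medical: pd.DataFrame,
                           window_days: int = COMPLICATION_WINDOW_DAYS) -> CvadRecord:
    """Attach complication events dated within [insertion, end + window].

    Category mapping: mechanical-complication diagnosis or a repair
    procedure -> MECHANICAL; partial/complete replacement procedure ->
    REPLACEMENT; catheter-infection diagnoses -> the two infection
    categories.
    """
    lo = device.insertion_date
    hi = device.in_place_end + pd.Timedelta(days=window_days)
    sub = medical[(medical["patient_id"] == device.patient_id)
                  & (medical["service_date"] >= lo)
                  & (medical["service_date"] <= hi)]
    dx_map = [
        (MECHANICAL, "dx", "mechanical"),
        (INFECTION_OTHER_UNSPEC, "dx", "infection_other"),
        (INFECTION_LOCAL, "dx", "infection_local"),
    ]
    events = []
    for _, row in sub.sort_values("service_date").iterrows():
        date = pd.Timestamp(row["service_date"])
        dxs = {str(row[c]) for c in DX_COLUMNS if pd.notna(row[c])}
        procs = {str(row[c]) for c in ("proc1", "proc2", "proc3") if pd.notna(row[c])}
        for category, _, role in dx_map:
            if dxs & _role_codes("dx", role):
                events.append(ComplicationEvent(date, category))
        if procs & _role_codes("proc", "repair"):
            events.append(ComplicationEvent(date, MECHANICAL))
        if procs & (_role_codes("proc", "replace_part") | _role_codes("proc", "replace_full")):
            events.append(ComplicationEvent(date, REPLACEMENT))
    device.complications = events
    return device


def build_cvads(dataset, cohort: pd.DataFrame,
                episode_config: EpisodeConfig = EPISODE_CONFIG,
                grace_days: int = 0,
                complication_window_days: int = COMPLICATION_WINDOW_DAYS) -> pd.DataFrame:
    """Full device pass: identify, flag relatedness, classify complications."""
    devices = identify_cvads(dataset.medical, dataset.enrollment, grace_days)
    index_by_pid = dict(zip(cohort["patient_id"], cohort["index_date"]))
    rows = []
    for dev in devices:
        idx = index_by_pid.get(dev.patient_id)
        if idx is not None and pd.notna(idx):
            use = medication_use_intervals(
                dataset.pharmacy[dataset.pharmacy["patient_id"] == dev.patient_id],
                episode_config)
            dev.related = is_related(dev, idx, use)
        classify_complications(dev, dataset.medical, complication_window_days)
        counts = {c: sum(e.category == c for e in dev.complications)
                  for c in COMPLICATION_CATEGORIES}
        rows.append({
            "patient_id": dev.patient_id,
            "insertion_date": dev.insertion_date,
            "removal_date": dev.removal_date,
            "in_place_end": dev.in_place_end,
            "in_place_days": dev.in_place_days,
            "related": dev.related,
            "n_complications": len(dev.complications),
            **{f"n_{c.lower()}": v for c, v in counts.items()},
        })
    return pd.DataFrame(rows, columns=[
        "patient_id", "insertion_date", "removal_date", "in_place_end",
        "in_place_days", "related", "n_complications",
        "n_mechanical", "n_replacement", "n_infection_other_unspec",
        "n_infection_local"])


def complication_summary(cvads: pd.DataFrame) -> dict:
    """Patient-level complication prevalence among related-CVAD users."""
    related = cvads[cvads["related"] == True]  # noqa: E712
    per_patient = related.groupby("patient_id").agg(
        any_compl=("n_complications", lambda s: int((s > 0).any())),
        mech=("n_mechanical", "sum"), repl=("n_replacement", "sum"),
        inf_other=("n_infection_other_unspec", "sum"),
        inf_local=("n_infection_local", "sum"))
    n = len(per_patient)
    def npct(k):
        cnt = int((per_patient[k] > 0).sum()) if n else 0
        return {"n": cnt, "pct": round(100.0 * cnt / n, 1) if n else None}
    return {
        "n_cvad_patients": n,
        "any_complication": npct("any_compl"),
        "mechanical": npct("mech"),
        "replacement": npct("repl"),
        "infection_other_unspec": npct("inf_other"),
        "infection_local": npct("inf_local"),
    }
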