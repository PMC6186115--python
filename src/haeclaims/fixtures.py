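"""Deterministic claims fixtures engineered to exercise every pipeline rule.

Each fixture is built constructively — explicit per-patient claim scripts
that satisfy (or violate) a rule definition by design, never by sampling —
so running the corresponding pipeline stage reproduces the fixture's target
counts exactly.  Shipped fixtures:

``F-COHORT``
    631 cohort-eligible patients whose medication combinations follow the
    seven mutually exclusive usage categories, plus three engineered
    exclusions (no HAE diagnosis; androgen-only therapy; insufficient
    post-index enrollment).
``F-EPI``
    155 patients holding 306 prophylactic C1-INH(IV) episodes, 163 of them
    with at least one rescue fill (53%).
``F-CVAD``
    18 related-port patients, 10 with at least one major complication
    (55.6%); category tallies 7 mechanical, 7 replacement, 2 other/
    unspecified infection, 1 local infection.
``F-TAB4``
    521 HCRU-eligible patients with stratified any-hospitalization /
    any-ED-visit counts: overall 79 and 271; C1-INH(IV) users (336) 68 and
    191; non-users (185) 11 and 80; CVAD users (18) 5 and 14; non-CVAD
    (503) 74 and 257; 477 patients with an office visit.
``F-ALL``
    The 631-patient master fixture: usage categories over all patients,
    the F-TAB4 utilization pattern on its 521 HCRU-eligible members, and
    the F-CVAD port/complication pattern on its 18 CVAD users.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .schema import (
    ANDROGEN,
    BERINERT,
    CINRYZE,
    ClaimsDataset,
    ECALLANTIDE,
    ED,
    HAE_DX_CODE,
    ICATIBANT,
    INPATIENT,
    OFFICE,
    OTHER,
)

INDEX_DAY = pd.Timestamp("2010-06-01")


class SpecificationError(ValueError):
    """A fixture spec's target counts are internally inconsistent."""


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    target_counts: tuple  # of (stratum label, numerator, denominator)

    def validate(self) -> "FixtureSpec":
        for label, num, den in self.target_counts:
            if not (isinstance(num, int) and isinstance(den, int)):
                raise SpecificationError(f"{self.name}/{label}: counts must be integers")
            if num < 0 or den < 0:
                raise SpecificationError(f"{self.name}/{label}: counts must be nonnegative")
            if num > den:
                raise SpecificationError(
                    f"{self.name}/{label}: numerator {num} exceeds denominator {den}")
        return self

    def count(self, label: str) -> tuple[int, int]:
        for lab, num, den in self.target_counts:
            if lab == label:
                return num, den
        raise KeyError(label)


FIXTURE_SPECS = {
    "F-COHORT": FixtureSpec("F-COHORT", (
        ("overall_cohort", 631, 631),
        ("sc_only", 197, 631),
        ("any_c1inh_iv", 434, 631),
        ("cinryze_only", 110, 631),
        ("cinryze_sc", 97, 631),
        ("berinert_only", 87, 631),
        ("berinert_sc", 53, 631),
        ("both_c1inh_sc", 49, 631),
        ("both_c1inh", 38, 631),
    )),
    "F-EPI": FixtureSpec("F-EPI", (
        ("prophylactic_episodes", 306, 306),
        ("episodes_with_rescue", 163, 306),
        ("patients_with_prophylaxis", 155, 155),
    )),
    "F-CVAD": FixtureSpec("F-CVAD", (
        ("any_complication", 10, 18),
        ("mechanical", 7, 18),
        ("replacement", 7, 18),
        ("infection_other_unspec", 2, 18),
        ("infection_local", 1, 18),
    )),
    "F-TAB4": FixtureSpec("F-TAB4", (
        ("hcru_cohort", 521, 521),
        ("overall_hosp", 79, 521),
        ("overall_ed", 271, 521),
        ("overall_office", 477, 521),
        ("c1inh_hosp", 68, 336),
        ("c1inh_ed", 191, 336),
        ("non_c1inh_hosp", 11, 185),
        ("non_c1inh_ed", 80, 185),
        ("cvad_hosp", 5, 18),
        ("cvad_ed", 14, 18),
        ("non_cvad_hosp", 74, 503),
        ("non_cvad_ed", 257, 503),
    )),
}

#: the seven mutually exclusive medication-usage categories with their
#: patient counts in the 631-patient master fixture
TABLE2_CATEGORY_COUNTS = {
    "sc_only": 197,
    "cinryze_only": 110,
    "cinryze_sc": 97,
    "berinert_only": 87,
    "berinert_sc": 53,
    "both_c1inh_sc": 49,
    "both_c1inh": 38,
}

FIXTURE_SPECS["F-ALL"] = FixtureSpec("F-ALL", tuple(
    list(FIXTURE_SPECS["F-COHORT"].target_counts)
    + list(FIXTURE_SPECS["F-TAB4"].target_counts)
    + list(FIXTURE_SPECS["F-CVAD"].target_counts)))


class _Builder:
    """Accumulates claim rows and assembles a schema-valid dataset."""

    def __init__(self):
        self.patients, self.enrollment, self.pharmacy, self.medical = [], [], [], []

    def patient(self, pid, sex="F", birth_year=1975, region="SOUTH",
                payer="COMMERCIAL", insurance="PPO", benefit="Y"):
        self.patients.append({
            "patient_id": pid, "sex": sex, "birth_year": birth_year,
            "region": region, "payer": payer, "insurance_type": insurance,
            "pharmacy_benefit": benefit})

    def enroll(self, pid, start, end):
        self.enrollment.append({"patient_id": pid, "span_start": pd.Timestamp(start),
                                "span_end": pd.Timestamp(end)})

    def fill(self, pid, date, product, iu=None, supply=None):
        self.pharmacy.append({"patient_id": pid, "fill_date": pd.Timestamp(date),
                              "product": product, "quantity_iu": iu,
                              "days_supply": supply})

    def med(self, pid, date, setting, dx1=None, proc1=None):
        self.medical.append({
            "patient_id": pid, "service_date": pd.Timestamp(date), "dx1": dx1,
            "dx2": None, "dx3": None, "proc1": proc1, "proc2": None,
            "proc3": None, "setting": setting})

    def build(self) -> ClaimsDataset:
        from .schema import (ENROLLMENT_COLUMNS, MEDICAL_COLUMNS,
                             PATIENT_COLUMNS, PHARMACY_COLUMNS)

        def frame(rows, cols, date_cols):
            df = pd.DataFrame(rows, columns=cols)
            for c in date_cols:
                df[c] = pd.to_datetime(df[c])
            return df
        return ClaimsDataset(
            patients=frame(self.patients, PATIENT_COLUMNS, []),
            enrollment=frame(self.enrollment, ENROLLMENT_COLUMNS,
                             ["span_start", "span_end"]),
            pharmacy=frame(self.pharmacy, PHARMACY_COLUMNS, ["fill_date"]),
            medical=frame(self.medical, MEDICAL_COLUMNS, ["service_date"]),
        ).validate()


def _category_fills(b: _Builder, pid, category: str, index=INDEX_DAY):
    """Emit the fills that place a patient in one usage category.

    Single fills only, so no refill run reaches the 13-week episode floor.
    """
    day = pd.Timestamp(index)
    if category == "sc_only":
        b.fill(pid, day, ICATIBANT)
    elif category == "cinryze_only":
        b.fill(pid, day, CINRYZE, iu=1500.0, supply=7)
    elif category == "cinryze_sc":
        b.fill(pid, day, CINRYZE, iu=1500.0, supply=7)
        b.fill(pid, day + pd.Timedelta(days=10), ICATIBANT)
    elif category == "berinert_only":
        b.fill(pid, day, BERINERT, iu=1500.0, supply=7)
    elif category == "berinert_sc":
        b.fill(pid, day, BERINERT, iu=1500.0, supply=7)
        b.fill(pid, day + pd.Timedelta(days=10), ECALLANTIDE)
    elif category == "both_c1inh_sc":
        b.fill(pid, day, CINRYZE, iu=1500.0, supply=7)
        b.fill(pid, day + pd.Timedelta(days=10), ICATIBANT)
        b.fill(pid, day + pd.Timedelta(days=60), BERINERT, iu=1500.0, supply=7)
    elif category == "both_c1inh":
        b.fill(pid, day, CINRYZE, iu=1500.0, supply=7)
        b.fill(pid, day + pd.Timedelta(days=60), BERINERT, iu=1500.0, supply=7)
    else:
        raise ValueError(f"unknown category {category!r}")


_CVAD_COMPLICATIONS = {
    # patient position (1-based among the 18 CVAD users) -> complication codes
    1: [("dx", "DX_MECH_COMPL"), ("dx", "DX_CVC_INFECT_OTHER")],
    2: [("dx", "DX_MECH_COMPL"), ("dx", "DX_CVC_INFECT_OTHER")],
    3: [("dx", "DX_MECH_COMPL"), ("dx", "DX_CVC_INFECT_LOCAL")],
    4: [("dx", "DX_MECH_COMPL"), ("proc", "REPLACE_FULL")],
    5: [("dx", "DX_MECH_COMPL"), ("proc", "REPLACE_FULL")],
    6: [("dx", "DX_MECH_COMPL"), ("proc", "REPLACE_FULL")],
    7: [("dx", "DX_MECH_COMPL"), ("proc", "REPLACE_FULL")],
    8: [("proc", "REPLACE_FULL")],
    9: [("proc", "REPLACE_FULL")],
    10: [("proc", "REPLACE_FULL")],
}


def _cvad_claims(b: _Builder, pid, position: int, index=INDEX_DAY):
    """Port inserted during C1-INH(IV) use, in place 98 days (related, B)."""
    day = pd.Timestamp(index)
    b.med(pid, day + pd.Timedelta(days=2), OTHER, proc1="INSERT_PORT")
    b.med(pid, day + pd.Timedelta(days=100), OTHER, proc1="REMOVE_PORT")
    for k, (kind, code) in enumerate(_CVAD_COMPLICATIONS.get(position, [])):
        cday = day + pd.Timedelta(days=20 + 10 * k)
        if kind == "dx":
            b.med(pid, cday, OTHER, dx1=code)
        else:
            b.med(pid, cday, OTHER, proc1=code)


def _build_cohort_fixture() -> ClaimsDataset:
    b = _Builder()
    i = 0
    for category, n in TABLE2_CATEGORY_COUNTS.items():
        for _ in range(n):
            i += 1
            pid = f"FC{i:04d}"
            b.patient(pid)
            b.enroll(pid, INDEX_DAY - pd.Timedelta(days=180),
                     INDEX_DAY + pd.Timedelta(days=400))
            b.med(pid, INDEX_DAY, OFFICE, dx1=HAE_DX_CODE)
            _category_fills(b, pid, category)
    # engineered exclusions
    b.patient("FX0001")  # HAE-specific fill but no recorded HAE diagnosis
    b.enroll("FX0001", INDEX_DAY - pd.Timedelta(days=180),
             INDEX_DAY + pd.Timedelta(days=400))
    b.fill("FX0001", INDEX_DAY, ICATIBANT)
    b.patient("FX0002")  # androgen-only therapy: never index-eligible
    b.enroll("FX0002", INDEX_DAY - pd.Timedelta(days=180),
             INDEX_DAY + pd.Timedelta(days=400))
    b.med("FX0002", INDEX_DAY, OFFICE, dx1=HAE_DX_CODE)
    b.fill("FX0002", INDEX_DAY, ANDROGEN, supply=30)
    b.patient("FX0003")  # enrollment ends 60 days after index (< 90)
    b.enroll("FX0003", INDEX_DAY - pd.Timedelta(days=180),
             INDEX_DAY + pd.Timedelta(days=60))
    b.med("FX0003", INDEX_DAY, OFFICE, dx1=HAE_DX_CODE)
    b.fill("FX0003", INDEX_DAY, ICATIBANT)
    return b.build()


def _build_epi_fixture() -> ClaimsDataset:
    """306 prophylactic episodes in 155 patients; rescue in the first 163.

    Each episode is 13 weekly fills of 1500 IU (days_supply 7), spanning
    exactly 91 days at exactly 1500 IU/week; successive episodes of one
    patient are separated by a 116-day refill silence, which breaks
    continuity at the default 45-day gap.
    """
    spec = FIXTURE_SPECS["F-EPI"].validate()
    n_rescue, n_episodes = spec.count("episodes_with_rescue")
    n_patients = spec.count("patients_with_prophylaxis")[0]
    b = _Builder()
    per_patient = [2] * (n_episodes - n_patients) + [1] * (2 * n_patients - n_episodes)
    global_idx = 0
    for p, k_eps in enumerate(per_patient, start=1):
        pid = f"FE{p:04d}"
        base = INDEX_DAY
        b.patient(pid)
        b.enroll(pid, base - pd.Timedelta(days=180), base + pd.Timedelta(days=600))
        b.med(pid, base, OFFICE, dx1=HAE_DX_CODE)
        for e in range(k_eps):
            ep_start = base + pd.Timedelta(days=200 * e)
            for w in range(13):
                b.fill(pid, ep_start + pd.Timedelta(days=7 * w), CINRYZE,
                       iu=1500.0, supply=7)
            if global_idx < n_rescue:
                b.fill(pid, ep_start + pd.Timedelta(days=30), ICATIBANT)
            global_idx += 1
    return b.build()


def _build_cvad_fixture() -> ClaimsDataset:
    b = _Builder()
    for p in range(1, 19):
        pid = f"FV{p:04d}"
        b.patient(pid)
        b.enroll(pid, INDEX_DAY - pd.Timedelta(days=180),
                 INDEX_DAY + pd.Timedelta(days=400))
        b.med(pid, INDEX_DAY, OFFICE, dx1=HAE_DX_CODE)
        b.fill(pid, INDEX_DAY, CINRYZE, iu=1500.0, supply=7)
        _cvad_claims(b, pid, p)
    return b.build()


def _tab4_flag_plan(n_users=336, n_nonusers=185, n_cvad=18):
    """Per-patient (c1inh, cvad, hosp, ed) booleans realizing the strata.

    Positions 1..n_cvad are CVAD users (within the C1-INH users); the
    stratified numerators decompose as 5+63+11 hospitalizations and
    14+177+80 ED visits.
    """
    plan = []
    for pos in range(1, n_users + n_nonusers + 1):
        c1 = pos <= n_users
        cvad = pos <= n_cvad
        if cvad:
            hosp, ed = pos <= 5, pos <= 14
        elif c1:
            rel = pos - n_cvad
            hosp, ed = rel <= 63, rel <= 177
        else:
            rel = pos - n_users
            hosp, ed = rel <= 11, rel <= 80
        plan.append((c1, cvad, hosp, ed))
    return plan


def _emit_tab4_patient(b: _Builder, pid, pos, c1, cvad, hosp, ed, office,
                       category=None, hcru_eligible=True):
    pre = 180 if hcru_eligible else 30
    b.patient(pid)
    b.enroll(pid, INDEX_DAY - pd.Timedelta(days=pre),
             INDEX_DAY + pd.Timedelta(days=400))
    b.med(pid, INDEX_DAY + pd.Timedelta(days=1), OTHER, dx1=HAE_DX_CODE)
    if category is not None:
        _category_fills(b, pid, category)
    elif c1:
        b.fill(pid, INDEX_DAY, CINRYZE, iu=1500.0, supply=7)
    else:
        b.fill(pid, INDEX_DAY, ICATIBANT)
    if cvad:
        _cvad_claims(b, pid, pos)
    if hosp:
        b.med(pid, INDEX_DAY + pd.Timedelta(days=40), INPATIENT, dx1=HAE_DX_CODE)
    if ed:
        b.med(pid, INDEX_DAY + pd.Timedelta(days=60), ED, dx1=HAE_DX_CODE)
    if office:
        b.med(pid, INDEX_DAY + pd.Timedelta(days=10), OFFICE, dx1="V70.0")


def _build_tab4_fixture() -> ClaimsDataset:
    spec = FIXTURE_SPECS["F-TAB4"].validate()
    n_office = spec.count("overall_office")[0]
    b = _Builder()
    for pos, (c1, cvad, hosp, ed) in enumerate(_tab4_flag_plan(), start=1):
        _emit_tab4_patient(b, f"FT{pos:04d}", pos, c1, cvad, hosp, ed,
                           office=pos <= n_office)
    return b.build()


def _build_all_fixture() -> ClaimsDataset:
    """Master fixture: usage categories x HCRU pattern x CVAD pattern.

    The 336 HCRU-eligible C1-INH(IV) users carry categories
    {cinryze_only x12, cinryze_sc x97, berinert_only x87, berinert_sc x53,
    both_c1inh_sc x49, both_c1inh x38}; 185 HCRU-eligible patients are
    SC-only.  The remaining 110 patients (98 cinryze_only, 12 sc_only) have
    only 30 days of pre-index enrollment, keeping them out of the HCRU
    cohort while they still satisfy the overall criteria.
    """
    b = _Builder()
    hcru_categories = (
        ["cinryze_only"] * 12 + ["cinryze_sc"] * 97 + ["berinert_only"] * 87
        + ["berinert_sc"] * 53 + ["both_c1inh_sc"] * 49 + ["both_c1inh"] * 38
        + ["sc_only"] * 185)
    n_office = FIXTURE_SPECS["F-TAB4"].count("overall_office")[0]
    plan = _tab4_flag_plan()
    for pos, ((c1, cvad, hosp, ed), category) in enumerate(
            zip(plan, hcru_categories), start=1):
        _emit_tab4_patient(b, f"FA{pos:04d}", pos, c1, cvad, hosp, ed,
                           office=pos <= n_office, category=category)
    extra = ["cinryze_only"] * 98 + ["sc_only"] * 12
    for k, category in enumerate(extra, start=len(plan) + 1):
        _emit_tab4_patient(b, f"FA{k:04d}", k, c1=False, cvad=False,
                           hosp=False, ed=False, office=False,
                           category=category, hcru_eligible=False)
    return b.build()


_BUILDERS = {
    "F-COHORT": _build_cohort_fixture,
    "F-EPI": _build_epi_fixture,
    "F-CVAD": _build_cvad_fixture,
    "F-TAB4": _build_tab4_fixture,
    "F-ALL": _build_all_fixture,
}


def generate_fixture(spec: FixtureSpec | str) -> ClaimsDataset:
    """Build the named fixture deterministically (no randomness involved)."""
    if isinstance(spec, FixtureSpec):
        spec.validate()
        name = spec.name
    else:
        name = spec
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_BUILDERS)}")
    FIXTURE_SPECS[name].validate()
    return _BUILDERS[name]()
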