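"""Claims-data schema: the four-table container every pipeline stage consumes.

The pipeline operates on patient-level administrative claims laid out in four
flat tables (patients, enrollment spans, pharmacy claims, medical claims).
Dates are ISO-8601 calendar dates; all durations are computed in integer days.
The documented column-level schema lives in ``docs/schema.md``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

# Pharmacy product vocabulary.  IU quantity is carried only for the two
# intravenous C1-inhibitor concentrates; other products carry unit counts.
CINRYZE = "CINRYZE"
BERINERT = "BERINERT"
ICATIBANT = "ICATIBANT"
ECALLANTIDE = "ECALLANTIDE"
ANDROGEN = "ANDROGEN"
TXA = "TXA"

#: Intravenous plasma-derived C1-inhibitor brands (dose-rate rule applies).
C1INH_IV_PRODUCTS = (CINRYZE, BERINERT)
#: Subcutaneous on-demand products.
SC_PRODUCTS = (ICATIBANT, ECALLANTIDE)
#: Products whose first fill fixes the medication index date.
HAE_SPECIFIC_PRODUCTS = C1INH_IV_PRODUCTS + SC_PRODUCTS
#: Everything a pharmacy claim may carry.
ALL_PRODUCTS = HAE_SPECIFIC_PRODUCTS + (ANDROGEN, TXA)

#: ICD-9-CM code for hereditary angioedema ("other deficiencies of
#: circulating enzymes"); matched dot-insensitively on any dx position.
HAE_DX_CODE = "277.6"

# Care-setting vocabulary for medical claims.
INPATIENT = "INPATIENT"
ED = "ED"
OFFICE = "OFFICE"
OTHER = "OTHER"
SETTINGS = (INPATIENT, ED, OFFICE, OTHER)

PATIENT_COLUMNS = [
    "patient_id", "sex", "birth_year", "region", "payer",
    "insurance_type", "pharmacy_benefit",
]
ENROLLMENT_COLUMNS = ["patient_id", "span_start", "span_end"]
PHARMACY_COLUMNS = ["patient_id", "fill_date", "product", "quantity_iu", "days_supply"]
MEDICAL_COLUMNS = [
    "patient_id", "service_date", "dx1", "dx2", "dx3",
    "proc1", "proc2", "proc3", "setting",
]

DX_COLUMNS = ["dx1", "dx2", "dx3"]
PROC_COLUMNS = ["proc1", "proc2", "proc3"]


class SchemaError(ValueError):
    """Raised when an input table violates the documented claims schema."""


def normalize_dx(code: object) -> str:
    """Normalize an ICD-9-CM code string for matching (strip dot, upper)."""
    if code is None or (isinstance(code, float) and pd.isna(code)):
        return ""
    return str(code).replace(".", "").strip().upper()


@dataclass
class ClaimsDataset:
    """In-memory claims dataset: the unit of exchange between stages."""

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    pharmacy: pd.DataFrame
    medical: pd.DataFrame

    # -- validation --------------------------------------------------------

    def validate(self) -> "ClaimsDataset":
        """Check column presence, dtypes, vocabularies and referential integrity."""
        for name, df, cols in [
            ("patients", self.patients, PATIENT_COLUMNS),
            ("enrollment", self.enrollment, ENROLLMENT_COLUMNS),
            ("pharmacy", self.pharmacy, PHARMACY_COLUMNS),
            ("medical", self.medical, MEDICAL_COLUMNS),
        ]:
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"table {name!r} missing columns {missing}")
        ids = set(self.patients["patient_id"])
        for name, df in [("enrollment", self.enrollment),
                         ("pharmacy", self.pharmacy),
                         ("medical", self.medical)]:
            orphans = set(df["patient_id"]) - ids
            if orphans:
                raise SchemaError(
                    f"table {name!r} references unknown patient ids "
                    f"(e.g. {sorted(orphans)[:3]})")
        bad = self.enrollment["span_end"] < self.enrollment["span_start"]
        if bad.any():
            raise SchemaError("enrollment span with end < start")
        unknown = ~self.pharmacy["product"].isin(ALL_PRODUCTS)
        if unknown.any():
            raise SchemaError(
                f"unknown products {sorted(self.pharmacy.loc[unknown, 'product'].unique())}")
        qty = pd.to_numeric(self.pharmacy["quantity_iu"], errors="coerce")
        if (qty.dropna() < 0).any():
            raise SchemaError("negative quantity_iu")
        unknown = ~self.medical["setting"].isin(SETTINGS)
        if unknown.any():
            raise SchemaError(
                f"unknown settings {sorted(self.medical.loc[unknown, 'setting'].unique())}")
        return self

    # -- IO ----------------------------------------------------------------

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = {
            "patients": self.patients,
            "enrollment": self.enrollment,
            "pharmacy": self.pharmacy,
            "medical": self.medical,
        }
        for name, df in frames.items():
            out = df.copy()
            for col in out.columns:
                if pd.api.types.is_datetime64_any_dtype(out[col]):
                    out[col] = out[col].dt.strftime("%Y-%m-%d")
            out.to_csv(outdir / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, indir: str | Path) -> "ClaimsDataset":
        indir = Path(indir)
        str_cols = {c: str for c in DX_COLUMNS + PROC_COLUMNS}
        patients = pd.read_csv(indir / "patients.csv")
        enrollment = pd.read_csv(indir / "enrollment.csv",
                                 parse_dates=["span_start", "span_end"])
        pharmacy = pd.read_csv(indir / "pharmacy.csv", parse_dates=["fill_date"])
        medical = pd.read_csv(indir / "medical.csv", parse_dates=["service_date"],
                              dtype=str_cols, keep_default_na=True)
        return cls(patients, enrollment, pharmacy, medical).validate()


def empty_dataset() -> ClaimsDataset:
    """A schema-valid dataset with zero rows (useful for edge-case tests)."""
    return ClaimsDataset(
        patients=pd.DataFrame(columns=PATIENT_COLUMNS),
        enrollment=pd.DataFrame(columns=ENROLLMENT_COLUMNS).astype(
            {"span_start": "datetime64[ns]", "span_end": "datetime64[ns]"}),
        pharmacy=pd.DataFrame(columns=PHARMACY_COLUMNS).astype(
            {"fill_date": "datetime64[ns]"}),
        medical=pd.DataFrame(columns=MEDICAL_COLUMNS).astype(
            {"service_date": "datetime64[ns]"}),
    )


def medical_has_dx(medical: pd.DataFrame, code: str = HAE_DX_CODE) -> pd.Series:
    """Boolean mask: claim carries `code` on any diagnosis position."""
    target = normalize_dx(code)
    mask = pd.Series(False, index=medical.index)
    for col in DX_COLUMNS:
        if col in medical.columns:
            mask |= medical[col].map(normalize_dx) == target
    return mask


def medical_has_proc(medical: pd.DataFrame, codes) -> pd.Series:
    """Boolean mask: claim carries any of `codes` on a procedure position."""
    codeset = {str(c) for c in codes}
    mask = pd.Series(False, index=medical.index)
    for col in PROC_COLUMNS:
        if col in medical.columns:
            mask |= medical[col].astype("string").fillna("").isin(codeset)
    return mask
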