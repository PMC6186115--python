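"""Charlson comorbidity index, Deyo ICD-9-CM adaptation.

Seventeen comorbidity categories are flagged from diagnosis codes observed
in the 6-month window before the medication index date (half-open:
[index - 180 d, index), so index-day diagnoses are excluded), then combined
with fixed weights {1,...,1,2,2,2,2,3,6,6} into a summary score predicting
one-year mortality risk.  Three hierarchy rules prevent double counting:
diabetes with complications supersedes uncomplicated diabetes,
moderate/severe liver disease supersedes mild liver disease, and metastatic
solid tumor supersedes any (non-metastatic) malignancy.

The category-to-ICD-9 mapping is shipped as an editable asset
(``data/deyo_icd9.csv``); codes are matched dot-insensitively by prefix so
the asset's 3-5 digit entries cover the code ranges of the published list.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources

import pandas as pd

from .schema import DX_COLUMNS, normalize_dx

logger = logging.getLogger(__name__)

PRE_INDEX_WINDOW_DAYS = 180

#: Deyo categories in canonical order with their fixed weights.
CATEGORY_WEIGHTS = {
    "mi": 1, "chf": 1, "pvd": 1, "cvd": 1, "dementia": 1, "cpd": 1,
    "rheum": 1, "pud": 1, "mild_liver": 1, "diabetes": 1,
    "diabetes_compl": 2, "plegia": 2, "renal": 2, "malignancy": 2,
    "severe_liver": 3, "mets": 6, "aids": 6,
}
CATEGORIES = list(CATEGORY_WEIGHTS)

#: (superseding category, superseded category)
HIERARCHY = [
    ("diabetes_compl", "diabetes"),
    ("severe_liver", "mild_liver"),
    ("mets", "malignancy"),
]

MAX_SCORE = sum(CATEGORY_WEIGHTS.values())  # with hierarchy the ceiling is lower


@lru_cache(maxsize=1)
def load_mapping() -> list[tuple[str, str]]:
    """(category, normalized code prefix) pairs from the shipped asset."""
    with resources.files("haeclaims.data").joinpath("deyo_icd9.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    pairs = []
    for _, row in df.iterrows():
        cat = row["category"]
        if cat not in CATEGORY_WEIGHTS:
            raise ValueError(f"unknown Deyo category {cat!r} in mapping asset")
        pairs.append((cat, normalize_dx(row["code_prefix"])))
    return pairs


def categorize_codes(codes) -> dict[str, bool]:
    """Flag Deyo categories for an iterable of raw ICD-9-CM code strings.

    Unrecognized codes are ignored (the claims stream is full of codes the
    index does not use); hierarchy rules are applied before returning.
    """
    mapping = load_mapping()
    flags = dict.fromkeys(CATEGORIES, False)
    for code in codes:
        norm = normalize_dx(code)
        if not norm:
            continue
        for cat, prefix in mapping:
            if norm.startswith(prefix):
                flags[cat] = True
    for winner, loser in HIERARCHY:
        if flags[winner]:
            flags[loser] = False
    return flags


def score_from_flags(flags: dict[str, bool]) -> int:
    return sum(CATEGORY_WEIGHTS[c] for c, v in flags.items() if v)


def cci_score(codes) -> int:
    """Deyo-weighted Charlson score for a bag of diagnosis codes."""
    return score_from_flags(categorize_codes(codes))


def cci_table(medical: pd.DataFrame, cohort: pd.DataFrame,
              window_days: int = PRE_INDEX_WINDOW_DAYS) -> pd.DataFrame:
    """Per-patient CCI over the pre-index window, for every cohort row.

    Diagnoses on claims dated in [index - window_days, index) contribute,
    regardless of claim setting or diagnosis position.
    """
    rows = []
    for _, rec in cohort.iterrows():
        pid, index_date = rec["patient_id"], pd.Timestamp(rec["index_date"])
        sub = medical[(medical["patient_id"] == pid)
                      & (medical["service_date"] >= index_date - pd.Timedelta(days=window_days))
                      & (medical["service_date"] < index_date)]
        codes = [c for col in DX_COLUMNS for c in sub[col].dropna()]
        flags = categorize_codes(codes)
        row = {"patient_id": pid, **{f"cci_{c}": flags[c] for c in CATEGORIES}}
        row["cci_score"] = score_from_flags(flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=(
        ["patient_id"] + [f"cci_{c}" for c in CATEGORIES] + ["cci_score"]))
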