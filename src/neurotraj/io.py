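"""Reading and validation of the visit / covariate CSV dialect.

Visits CSV: subject_id, age_years, group, field_strength (1.5 or 3.0),
is_duplicate (0/1), region_1..region_K.  Covariates CSV: subject_id,
sex_female (0/1), apoe4_count (0/1/2), education_years.  Comma-separated,
UTF-8, header row, '.' decimal, ages in floating-point years.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

VISIT_REQUIRED = ("subject_id", "age_years", "group", "field_strength",
                  "is_duplicate")
COVARIATE_REQUIRED = ("subject_id", "sex_female", "apoe4_count",
                      "education_years")


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def _bad_rows(mask: pd.Series) -> list[int]:
    # 1-based data row numbers (header is row 0), matching what a user sees
    return [int(i) + 2 for i in np.nonzero(mask.to_numpy())[0]]


def validate_visits(visits: pd.DataFrame) -> pd.DataFrame:
    _check_columns(visits, VISIT_REQUIRED, "visits table")
    regions = [c for c in visits.columns if c.startswith("region_")]
    if not regions:
        raise ValueError("visits table has no region_* feature columns")
    age = pd.to_numeric(visits["age_years"], errors="coerce")
    bad = age.isna() | ~np.isfinite(age)
    if bad.any():
        raise ValueError(f"non-numeric age_years in rows {_bad_rows(bad)}")
    visits = visits.assign(age_years=age)
    bad_field = ~visits["field_strength"].isin([1.5, 3.0])
    if bad_field.any():
        raise ValueError(
            f"field_strength must be 1.5 or 3.0; bad rows {_bad_rows(bad_field)}")
    dup = visits.loc[visits["is_duplicate"] == 0]
    repeated = dup.duplicated(subset=["subject_id", "age_years"], keep=False)
    if repeated.any():
        warnings.warn(
            "rows sharing (subject, age) are not flagged is_duplicate: "
            f"rows {_bad_rows(repeated)}", stacklevel=2)
    return visits


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    _check_columns(cov, COVARIATE_REQUIRED, "covariate table")
    bad_apoe = ~cov["apoe4_count"].isin([0, 1, 2])
    if bad_apoe.any():
        raise ValueError(
            f"apoe4_count must be 0, 1 or 2; bad rows {_bad_rows(bad_apoe)}")
    bad_sex = ~cov["sex_female"].isin([0, 1])
    if bad_sex.any():
        raise ValueError(
            f"sex_female must be 0 or 1; bad rows {_bad_rows(bad_sex)}")
    if cov["subject_id"].duplicated().any():
        dups = cov.loc[cov["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject_id in covariate table: {dups}")
    return cov


def read_visits(path) -> pd.DataFrame:
    return validate_visits(pd.read_csv(path))


def read_covariates(path) -> pd.DataFrame:
    return validate_covariates(pd.read_csv(path))
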