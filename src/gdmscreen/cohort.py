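"""Cohort table schema, validation and CSV round-trip.

A cohort is a :class:`pandas.DataFrame` with one row per pregnancy and a
fixed column set (see :data:`SCHEMA`). Missing covariate values are plain
``NaN`` (empty cells in CSV); the binary outcome column ``gdm`` must always
be complete. All downstream stages — simulation, imputation, scoring,
evaluation — exchange this one representation.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

ETHNICITY_LEVELS = ("caucasian", "african", "asian", "mixed", "other")
EDUCATION_LEVELS = ("low", "medium", "high")
CONCEPTION_LEVELS = ("spontaneous", "ovulation_drugs", "ivf")

#: column -> kind; kinds: continuous, categorical, binary, count, outcome
SCHEMA: dict[str, str] = {
    "age_years": "continuous",
    "height_cm": "continuous",
    "weight_kg": "continuous",
    "bmi": "continuous",
    "sbp_mmhg": "continuous",
    "glucose_mmol_l": "continuous",
    "ethnicity": "categorical",
    "education": "categorical",
    "smoking": "binary",
    "family_history_dm": "binary",
    "conception": "categorical",
    "parity": "count",
    "history_gdm": "binary",
    "history_macrosomia": "binary",
    "gdm": "outcome",
}

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "ethnicity": ETHNICITY_LEVELS,
    "education": EDUCATION_LEVELS,
    "conception": CONCEPTION_LEVELS,
}

COLUMNS = tuple(SCHEMA)
OUTCOME = "gdm"

#: |bmi - weight/(height/100)^2| tolerated before a validation warning
BMI_TOLERANCE = 0.1


class CohortValidationError(ValueError):
    """A cohort table violates the schema or a domain invariant."""


def validate_cohort(
    df: pd.DataFrame,
    *,
    allow_missing: bool = True,
    required_columns: tuple[str, ...] | None = None,
) -> list[str]:
    """Validate a cohort table against the schema.

    Parameters
    ----------
    df
        Candidate cohort table.
    allow_missing
        If False, any NaN in a covariate raises.
    required_columns
        Columns that must be present; defaults to the full schema. A
        cohort missing an optional continuous column (e.g. ``sbp_mmhg``
        when no loaded model uses it) can pass a reduced tuple.

    Returns
    -------
    list of str
        Non-fatal warnings (e.g. BMI/height/weight inconsistencies with
        the offending row indices). Fatal problems raise
        :class:`CohortValidationError`.
    """
    required = required_columns if required_columns is not None else COLUMNS
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing required columns: {missing_cols}")
    unknown = [c for c in df.columns if c not in SCHEMA]
    if unknown:
        raise CohortValidationError(f"unknown columns: {unknown}")
    if OUTCOME in df.columns:
        if df[OUTCOME].isna().any():
            raise CohortValidationError("outcome column 'gdm' contains missing values")
        bad = set(pd.unique(df[OUTCOME])) - {0, 1}
        if bad:
            raise CohortValidationError(f"outcome 'gdm' must be 0/1, found {sorted(bad)}")

    warnings: list[str] = []
    for col, levels in CATEGORY_LEVELS.items():
        if col not in df.columns:
            continue
        observed = df[col].dropna()
        bad_levels = set(observed.unique()) - set(levels)
        if bad_levels:
            raise CohortValidationError(
                f"column {col!r} has unknown levels {sorted(bad_levels)}; allowed {levels}"
            )
    for col in df.columns:
        kind = SCHEMA[col]
        series = df[col]
        if kind == "binary":
            bad = set(pd.unique(series.dropna())) - {0, 1}
            if bad:
                raise CohortValidationError(f"binary column {col!r} has values {sorted(bad)}")
        elif kind == "count":
            observed = series.dropna()
            if ((observed < 0) | (observed != observed.astype(int))).any():
                raise CohortValidationError(f"count column {col!r} must be non-negative integers")
        if not allow_missing and col != OUTCOME and series.isna().any():
            raise CohortValidationError(f"column {col!r} contains missing values")

    if "glucose_mmol_l" in df.columns:
        observed = df["glucose_mmol_l"].dropna()
        if (observed <= 0).any():
            raise CohortValidationError("glucose_mmol_l must be strictly positive")

    if {"height_cm", "weight_kg", "bmi"}.issubset(df.columns):
        h = df["height_cm"].to_numpy(dtype=float)
        w = df["weight_kg"].to_numpy(dtype=float)
        b = df["bmi"].to_numpy(dtype=float)
        complete = ~(np.isnan(h) | np.isnan(w) | np.isnan(b))
        with np.errstate(invalid="ignore", divide="ignore"):
            resid = np.abs(b - w / (h / 100.0) ** 2)
        bad_rows = np.flatnonzero(complete & (resid > BMI_TOLERANCE))
        if bad_rows.size:
            warnings.append(
                "bmi inconsistent with weight/height beyond "
                f"{BMI_TOLERANCE} kg/m^2 in rows {bad_rows.tolist()[:20]}"
                + ("..." if bad_rows.size > 20 else "")
            )

    if {"parity", "history_gdm", "history_macrosomia"}.issubset(df.columns):
        parous0 = df["parity"] == 0
        for col in ("history_gdm", "history_macrosomia"):
            viol = parous0 & (df[col] == 1)
            if viol.any():
                raise CohortValidationError(
                    f"{col} is true for nulliparous rows {df.index[viol].tolist()[:20]}"
                )
    return warnings


def read_cohort_csv(path: str | Path | io.IOBase, **validate_kwargs) -> pd.DataFrame:
    """Read and validate a cohort CSV (empty cells are missing values)."""
    df = pd.read_csv(path)
    for col in df.columns:
        if SCHEMA.get(col) in ("binary", "outcome", "count") and df[col].notna().all():
            df[col] = df[col].astype(int)
    validate_cohort(df, **validate_kwargs)
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table to CSV with missing values as empty cells."""
    df.to_csv(path, index=False, na_rep="")
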