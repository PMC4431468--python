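"""Cohort container and delimited-file I/O.

A cohort is one row per subject with demographics, anthropometrics, blood
pressure, skin reflectance (SR, percent of reflected UV light, a proxy for
skin pigmentation), skin autofluorescence (SAF, arbitrary units, a proxy for
tissue advanced glycation endproducts) and disease/lifestyle flags.

SAF cannot be measured on skin with SR below 6%: rows violating this are kept
but flagged invalid (``sr_valid`` False) so downstream stages can exclude
them explicitly rather than silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "CohortSchemaError",
    "CohortParseError",
    "EXERCISE_LEVELS",
    "MANDATORY_COLUMNS",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

#: Ordered physical-activity levels used throughout (questionnaire categories).
EXERCISE_LEVELS = ["none", "1-2/month", "1-2/week", "3+/week"]

#: Minimum skin reflectance (percent) at which a SAF reading is valid.
SR_MIN_VALID = 6.0

MANDATORY_COLUMNS = [
    "id", "gender", "age", "nationality", "height", "weight", "bmi",
    "waist", "hip", "whr", "sbp", "dbp", "sr", "saf",
    "diabetes", "hypertension", "smoking", "exercise",
]

_NUMERIC = ["age", "height", "weight", "bmi", "waist", "hip", "whr",
            "sbp", "dbp", "sr", "saf"]
_FLAGS = ["diabetes", "hypertension", "smoking"]


class CohortSchemaError(ValueError):
    """A mandatory column is missing or mistyped."""


class CohortParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""


@dataclass
class Cohort:
    """Ordered collection of subject records plus provenance.

    ``df`` holds one row per subject with at least :data:`MANDATORY_COLUMNS`;
    unknown extra columns are preserved untouched.
    """

    df: pd.DataFrame
    provenance: str = ""
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValueError("cohort must be non-empty")
        if self.df["id"].duplicated().any():
            dupes = self.df.loc[self.df["id"].duplicated(), "id"].tolist()[:5]
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def men(self) -> pd.DataFrame:
        return self.df[self.df["gender"] == "M"]

    @property
    def women(self) -> pd.DataFrame:
        return self.df[self.df["gender"] == "F"]


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Check subject-level invariants; returns human-readable warnings.

    Adds/overwrites a boolean ``sr_valid`` column (False where SR < 6%, the
    instrument's validity floor). Hard invariant violations raise.
    """
    msgs: list[str] = []
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {missing}")
    if (df["age"] < 18).any():
        raise ValueError("age must be >= 18 for every subject")
    if (df["saf"] <= 0).any():
        raise ValueError("saf must be positive")
    bad_gender = ~df["gender"].isin(["M", "F"])
    if bad_gender.any():
        raise ValueError(f"gender must be M or F (rows {list(df.index[bad_gender])[:5]})")

    # relative consistency of derived quantities (0.5% tolerance)
    bmi_ref = df["weight"] / df["height"] ** 2
    if not np.allclose(df["bmi"], bmi_ref, rtol=5e-3):
        raise ValueError("bmi inconsistent with weight/height^2 beyond 0.5%")
    whr_ref = df["waist"] / df["hip"]
    if not np.allclose(df["whr"], whr_ref, rtol=5e-3):
        raise ValueError("whr inconsistent with waist/hip beyond 0.5%")

    invalid_sr = df["sr"] < SR_MIN_VALID
    df["sr_valid"] = ~invalid_sr
    if invalid_sr.any():
        rows = list(df.index[invalid_sr])
        msg = (f"{invalid_sr.sum()} row(s) have SR below {SR_MIN_VALID}% where no "
               f"valid SAF measurement is possible; flagged sr_valid=False "
               f"(rows {rows[:10]})")
        msgs.append(msg)
        warnings.warn(msg)
    return msgs


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as a delimited UTF-8 table ('.tsv' → tab, else comma)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    cohort.df.to_csv(path, sep=sep, index=False)


def read_cohort(path, provenance: str | None = None) -> Cohort:
    """Read a delimited cohort table written by :func:`write_cohort`.

    Write→read round trips are identity on every field; unknown columns are
    preserved as opaque extras.  Missing mandatory columns raise
    :class:`CohortSchemaError` naming the column; unparseable numeric cells
    raise :class:`CohortParseError` with the row index.
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str}, keep_default_na=True,
                     na_values=[""], float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {missing}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise CohortParseError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    df["age"] = df["age"].astype(int)
    for col in _FLAGS:
        df[col] = df[col].astype(str).str.lower().isin(["true", "1", "yes"])
    if "sr_valid" in df.columns:
        df["sr_valid"] = df["sr_valid"].astype(str).str.lower().isin(["true", "1"])
    msgs = validate_cohort(df)
    return Cohort(df=df, provenance=provenance or f"read from {path}", warnings=msgs)
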