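"""Register-style tabular data: reading, validation, filtering and timing traits.

The data dictionary is a flat CSV, one row per individual::

    person_id,sex,birth_year,education,n_children,first_child_year,last_child_year,age_at_death

Empty fields mean "absent". ``sex`` is ``F`` or ``M``; ``education`` is one of
``primary, secondary, vocational, tertiary, unknown``. Ages are whole-year
differences of calendar years because the register supplies birth years only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("F", "M")
EDUCATION_LEVELS = ("primary", "secondary", "vocational", "tertiary", "unknown")
#: Education levels that enter education-stratified analyses (``unknown`` is
#: retained for cohort means and standardization but never forms a stratum).
KNOWN_EDUCATION_LEVELS = ("primary", "secondary", "vocational", "tertiary")

REGISTER_COLUMNS = (
    "person_id",
    "sex",
    "birth_year",
    "education",
    "n_children",
    "first_child_year",
    "last_child_year",
    "age_at_death",
)

TRAITS = ("AFB", "ALB", "IBI")


class RegisterError(ValueError):
    """Base class for register data problems."""


class RegisterParseError(RegisterError):
    """A field could not be interpreted (bad token, bad header, bad number)."""


class RegisterValidationError(RegisterError):
    """Fields parsed but violate a record invariant."""


@dataclass(frozen=True)
class IndividualRecord:
    """One register row.

    ``first_child_year``/``last_child_year`` are present iff ``n_children >= 1``;
    ``age_at_death`` is present only when a death age was recorded.
    """

    person_id: str
    sex: str
    birth_year: int
    education: str
    n_children: int
    first_child_year: Optional[int] = None
    last_child_year: Optional[int] = None
    age_at_death: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RegisterParseError(f"unknown sex token {self.sex!r}")
        if self.education not in EDUCATION_LEVELS:
            raise RegisterParseError(f"unknown education token {self.education!r}")
        if self.n_children < 0:
            raise RegisterValidationError("n_children must be non-negative")
        parous = self.n_children >= 1
        has_years = self.first_child_year is not None and self.last_child_year is not None
        if parous and not has_years:
            raise RegisterValidationError(
                f"person {self.person_id}: n_children >= 1 but child years missing"
            )
        if not parous and (self.first_child_year is not None or self.last_child_year is not None):
            raise RegisterValidationError(
                f"person {self.person_id}: childless record carries child years"
            )
        if has_years:
            if self.last_child_year < self.first_child_year:
                raise RegisterValidationError(
                    f"person {self.person_id}: last_child_year < first_child_year"
                )
            if self.n_children == 1 and self.first_child_year != self.last_child_year:
                raise RegisterValidationError(
                    f"person {self.person_id}: single child but first != last child year"
                )
            if self.first_child_year <= self.birth_year:
                raise RegisterValidationError(
                    f"person {self.person_id}: first_child_year not after birth_year"
                )
        if self.age_at_death is not None and self.age_at_death < 0:
            raise RegisterValidationError(f"person {self.person_id}: negative age_at_death")


@dataclass(frozen=True)
class TimingTraits:
    """Reproductive-timing traits of a parous individual.

    ``afb``/``alb`` are ages at first/last birth in whole years. ``ibi`` is the
    average interbirth interval, (alb − afb) / n_children, defined only for
    individuals with at least two children.
    """

    afb: int
    alb: int
    ibi: Optional[float] = None


@dataclass(frozen=True)
class FilterPolicy:
    """Inclusion rules: birth-cohort window and survival to a minimum age.

    Individuals with no recorded death age count as having survived; the
    survival rule is inclusive (death at exactly ``min_survival_age`` is kept).
    """

    min_birth_year: int = 1925
    max_birth_year: int = 1977
    min_survival_age: int = 15

    def __post_init__(self) -> None:
        if self.min_birth_year > self.max_birth_year:
            raise ValueError("min_birth_year must be <= max_birth_year")
        if self.min_survival_age < 0:
            raise ValueError("min_survival_age must be >= 0")


_OPTIONAL_INT_COLS = ("first_child_year", "last_child_year", "age_at_death")


def validate_register(df: pd.DataFrame) -> None:
    """Raise if *df* violates the data dictionary or a record invariant.

    Error messages carry 1-based data row numbers (header not counted).
    """
    missing = [c for c in REGISTER_COLUMNS if c not in df.columns]
    if missing:
        raise RegisterParseError(f"missing columns: {missing}")

    def _rows(mask: pd.Series) -> str:
        rows = (np.flatnonzero(mask.to_numpy()) + 1)[:5].tolist()
        return f"rows {rows}"

    bad = ~df["sex"].isin(SEXES)
    if bad.any():
        tok = df.loc[bad, "sex"].iloc[0]
        raise RegisterParseError(f"unknown sex token {tok!r} ({_rows(bad)}, field 'sex')")
    bad = ~df["education"].isin(EDUCATION_LEVELS)
    if bad.any():
        tok = df.loc[bad, "education"].iloc[0]
        raise RegisterParseError(
            f"unknown education token {tok!r} ({_rows(bad)}, field 'education')"
        )
    for col in ("birth_year", "n_children"):
        if df[col].isna().any():
            raise RegisterParseError(f"column {col!r} has empty fields ({_rows(df[col].isna())})")
    if (df["n_children"] < 0).any():
        raise RegisterValidationError(f"negative n_children ({_rows(df['n_children'] < 0)})")

    parous = df["n_children"] >= 1
    fc, lc = df["first_child_year"], df["last_child_year"]
    bad = parous & (fc.isna() | lc.isna())
    if bad.any():
        raise RegisterValidationError(f"parous record missing child years ({_rows(bad)})")
    bad = ~parous & (fc.notna() | lc.notna())
    if bad.any():
        raise RegisterValidationError(f"childless record carries child years ({_rows(bad)})")
    both = fc.notna() & lc.notna()
    bad = both & (lc < fc)
    if bad.any():
        raise RegisterValidationError(f"last_child_year < first_child_year ({_rows(bad)})")
    bad = (df["n_children"] == 1) & both & (fc != lc)
    if bad.any():
        raise RegisterValidationError(f"single child but first != last child year ({_rows(bad)})")
    bad = both & (fc <= df["birth_year"])
    if bad.any():
        raise RegisterValidationError(f"first_child_year not after birth_year ({_rows(bad)})")
    if (df["age_at_death"].dropna() < 0).any():
        raise RegisterValidationError("negative age_at_death")


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["person_id"] = out["person_id"].astype(str)
    out["birth_year"] = out["birth_year"].astype("int64")
    out["n_children"] = out["n_children"].astype("int64")
    for col in _OPTIONAL_INT_COLS:
        out[col] = out[col].astype("Int64")
    return out


def read_register(path: str | Path) -> pd.DataFrame:
    """Read and validate a register CSV, preserving row order.

    Absent fields become pandas ``<NA>`` in nullable-integer columns, never
    sentinel numbers.
    """
    try:
        df = pd.read_csv(
            path,
            dtype={
                "person_id": str,
                "sex": str,
                "education": str,
                "birth_year": "Int64",
                "n_children": "Int64",
                "first_child_year": "Int64",
                "last_child_year": "Int64",
                "age_at_death": "Int64",
            },
        )
    except ValueError as exc:  # non-integer token in an integer column
        raise RegisterParseError(f"{path}: {exc}") from exc
    validate_register(df)
    return _coerce_dtypes(df)


def write_register(df: pd.DataFrame, path: str | Path) -> None:
    """Write a register CSV in the documented dialect (empty field = absent)."""
    out = _coerce_dtypes(df)[list(REGISTER_COLUMNS)]
    out.to_csv(path, index=False)


def records_to_frame(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    rows = [
        (
            r.person_id,
            r.sex,
            r.birth_year,
            r.education,
            r.n_children,
            r.first_child_year,
            r.last_child_year,
            r.age_at_death,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(REGISTER_COLUMNS))
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype="object") for c in REGISTER_COLUMNS})
        df["birth_year"] = df["birth_year"].astype("int64")
        df["n_children"] = df["n_children"].astype("int64")
    return _coerce_dtypes(df)


def frame_to_records(df: pd.DataFrame) -> list[IndividualRecord]:
    def _opt(v) -> Optional[int]:
        return None if pd.isna(v) else int(v)

    return [
        IndividualRecord(
            person_id=str(row.person_id),
            sex=row.sex,
            birth_year=int(row.birth_year),
            education=row.education,
            n_children=int(row.n_children),
            first_child_year=_opt(row.first_child_year),
            last_child_year=_opt(row.last_child_year),
            age_at_death=_opt(row.age_at_death),
        )
        for row in df.itertuples(index=False)
    ]


def apply_filters(df: pd.DataFrame, policy: FilterPolicy = FilterPolicy()) -> pd.DataFrame:
    """Apply the cohort-window and survival rules; log removals per rule.

    Idempotent: re-applying the same policy is a no-op.
    """
    in_window = df["birth_year"].between(policy.min_birth_year, policy.max_birth_year)
    survived = df["age_at_death"].isna() | (df["age_at_death"] >= policy.min_survival_age)
    logger.info(
        "apply_filters: removed %d outside birth years %d-%d, %d dying before age %d",
        int((~in_window).sum()),
        policy.min_birth_year,
        policy.max_birth_year,
        int((in_window & ~survived).sum()),
        policy.min_survival_age,
    )
    return df.loc[in_window & survived].copy()


def derive_timing(record: IndividualRecord) -> Optional[TimingTraits]:
    """Timing traits for one record; ``None`` for childless individuals."""
    if record.n_children == 0:
        return None
    afb = int(record.first_child_year) - record.birth_year
    alb = int(record.last_child_year) - record.birth_year
    ibi = (alb - afb) / record.n_children if record.n_children >= 2 else None
    return TimingTraits(afb=afb, alb=alb, ibi=ibi)


def add_timing(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *df* with float columns ``AFB``, ``ALB``, ``IBI``.

    Values are NaN where the trait is undefined (childless for AFB/ALB;
    fewer than two children for IBI). One-child parents are excluded from IBI
    rather than assigned a zero interval; the exclusion count is logged.
    """
    out = df.copy()
    afb = (out["first_child_year"] - out["birth_year"]).astype("Float64").astype(float)
    alb = (out["last_child_year"] - out["birth_year"]).astype("Float64").astype(float)
    out["AFB"] = afb
    out["ALB"] = alb
    multiparous = out["n_children"] >= 2
    ibi = np.where(multiparous, (alb - afb) / out["n_children"].to_numpy(), np.nan)
    out["IBI"] = ibi
    n_single = int((out["n_children"] == 1).sum())
    if n_single:
        logger.info("add_timing: %d one-child parents have no defined IBI", n_single)
    return out
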