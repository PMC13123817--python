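"""Shared domain tables, validation, and CSV readers/writers.

The pipeline's common currency is the long-format "demographic frame": a
:class:`pandas.DataFrame` in one of four table kinds, mirroring how the UN
World Population Prospects distributes its estimates:

``population``
    region_id, year, age, sex, count — person counts by single completed age.
``births``
    region_id, year, sex_of_child, mother_age, count — birth counts by sex of
    the child and single maternal age (``mother_age`` may be ``"all"`` for a
    marginal row; ``sex_of_child`` may be ``"all"`` likewise).
``lifetable``
    region_id, year, sex, age, p — period life-table survival probabilities,
    ``p`` being the probability of surviving from exact age x to x+1.
``fertility``
    region_id, year, tfr_female, tfr_male — period total fertility rates;
    ``tfr_male`` is optional (present only for training/validation data).

Conventions used throughout the package: ages are completed years, age
ranges are closed/inclusive at both ends, the open-ended top age ("100+") is
stored as age 100, logarithms are natural, and CSV is the interchange format
(UTF-8, one table kind per file).
"""

from __future__ import annotations

import enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableKind",
    "SchemaError",
    "ValidationError",
    "DomainError",
    "MissingDataError",
    "COLUMNS",
    "SEXES",
    "MAX_AGE",
    "read_frame",
    "write_frame",
    "validate_frame",
    "adult_sex_ratio",
]

SEXES = ("male", "female")
MAX_AGE = 110  # hard upper bound for a completed age in any table
MOTHER_AGE_RANGE = (10, 60)

_ALL_TOLERANCE = 1e-9  # relative tolerance for "all"-row consistency


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(ValueError):
    """A row violates a table invariant; the message names row and rule."""


class DomainError(ValueError):
    """An operation was called on values outside its mathematical domain."""


class MissingDataError(ValueError):
    """Required ages/rows are absent; the message lists what is missing."""


class TableKind(str, enum.Enum):
    POPULATION = "population"
    BIRTHS = "births"
    LIFETABLE = "lifetable"
    FERTILITY = "fertility"


COLUMNS: Mapping[TableKind, tuple[str, ...]] = {
    TableKind.POPULATION: ("region_id", "year", "age", "sex", "count"),
    TableKind.BIRTHS: ("region_id", "year", "sex_of_child", "mother_age", "count"),
    TableKind.LIFETABLE: ("region_id", "year", "sex", "age", "p"),
    TableKind.FERTILITY: ("region_id", "year", "tfr_female", "tfr_male"),
}


def _as_kind(kind: TableKind | str) -> TableKind:
    return TableKind(kind)


def _require_columns(df: pd.DataFrame, kind: TableKind) -> None:
    required = COLUMNS[kind] if kind is not TableKind.FERTILITY else COLUMNS[kind][:3]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{kind.value} table is missing required column {col!r}")


def _check(condition: pd.Series, rule: str) -> None:
    bad = condition.index[~condition.to_numpy()]
    if len(bad):
        rows = ", ".join(str(i) for i in bad[:10])
        raise ValidationError(f"rows [{rows}] violate rule: {rule}")


def _parse_mother_age(values: pd.Series) -> pd.Series:
    def one(v):
        if isinstance(v, str) and v.strip().lower() == "all":
            return "all"
        try:
            f = float(v)
        except (TypeError, ValueError):
            raise ValidationError(f"mother_age {v!r} is neither an integer nor 'all'")
        if f != int(f):
            raise ValidationError(f"mother_age {v!r} is not an integer age")
        return int(f)

    return values.map(one)


def validate_frame(df: pd.DataFrame, kind: TableKind | str) -> pd.DataFrame:
    """Coerce dtypes and enforce the invariants of *kind*; return the frame.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for invariant violations (the message names the
    offending rows and the rule).
    """
    kind = _as_kind(kind)
    _require_columns(df, kind)
    df = df.copy()
    df["region_id"] = df["region_id"].astype(str)
    df["year"] = pd.to_numeric(df["year"]).astype(int)

    if kind is TableKind.POPULATION:
        df["age"] = pd.to_numeric(df["age"]).astype(int)
        df["sex"] = df["sex"].astype(str)
        df["count"] = pd.to_numeric(df["count"]).astype(float)
        _check(df["sex"].isin(SEXES), f"sex must be one of {SEXES}")
        _check(df["count"] >= 0, "count must be non-negative")
        _check(df["age"].between(0, MAX_AGE), f"age must lie in [0, {MAX_AGE}]")
        dup = df.duplicated(subset=["region_id", "year", "age", "sex"], keep=False)
        _check(~dup, "(region_id, year, age, sex) must be unique")

    elif kind is TableKind.BIRTHS:
        df["sex_of_child"] = df["sex_of_child"].astype(str)
        df["mother_age"] = _parse_mother_age(df["mother_age"])
        df["count"] = pd.to_numeric(df["count"]).astype(float)
        _check(df["sex_of_child"].isin(SEXES + ("all",)), "sex_of_child must be male/female/all")
        _check(df["count"] >= 0, "count must be non-negative")
        lo, hi = MOTHER_AGE_RANGE
        ok = df["mother_age"].map(lambda a: a == "all" or lo <= a <= hi).astype(bool)
        _check(ok, f"mother_age must be 'all' or lie in [{lo}, {hi}]")
        _check_all_rows_consistent(df)

    elif kind is TableKind.LIFETABLE:
        df["age"] = pd.to_numeric(df["age"]).astype(int)
        df["sex"] = df["sex"].astype(str)
        df["p"] = pd.to_numeric(df["p"]).astype(float)
        _check(df["sex"].isin(SEXES), f"sex must be one of {SEXES}")
        _check(df["p"].between(0.0, 1.0), "survival probability p must lie in [0, 1]")
        for (region, year, sex), grp in df.groupby(["region_id", "year", "sex"]):
            ages = np.sort(grp["age"].unique())
            if len(ages) != len(grp) or not np.array_equal(ages, np.arange(0, ages[-1] + 1)):
                raise ValidationError(
                    f"life table for ({region}, {year}, {sex}) must cover contiguous "
                    f"ages from 0 without duplicates"
                )

    elif kind is TableKind.FERTILITY:
        df["tfr_female"] = pd.to_numeric(df["tfr_female"]).astype(float)
        if "tfr_male" not in df.columns:
            df["tfr_male"] = np.nan
        df["tfr_male"] = pd.to_numeric(df["tfr_male"]).astype(float)
        _check(df["tfr_female"] >= 0, "tfr_female must be non-negative")
        _check(df["tfr_male"].isna() | (df["tfr_male"] >= 0), "tfr_male must be non-negative when present")

    return df


def _check_all_rows_consistent(df: pd.DataFrame) -> None:
    """Where both an 'all' mother_age row and single-age rows exist, the
    single-age counts must sum to the 'all' row (relative tolerance 1e-9)."""
    for (region, year, sex), grp in df.groupby(["region_id", "year", "sex_of_child"]):
        is_all = grp["mother_age"] == "all"
        if is_all.any() and (~is_all).any():
            total = grp.loc[is_all, "count"].sum()
            summed = grp.loc[~is_all, "count"].sum()
            if abs(summed - total) > _ALL_TOLERANCE * max(1.0, abs(total)):
                raise ValidationError(
                    f"births for ({region}, {year}, {sex}): single-age counts sum to "
                    f"{summed!r} but the 'all' row states {total!r}"
                )


def read_frame(path, kind: TableKind | str) -> pd.DataFrame:
    """Read and validate a demographic CSV table; row order is preserved."""
    kind = _as_kind(kind)
    # round_trip parsing: the default fast parser is not correctly rounded,
    # which would break write->read float equality
    df = pd.read_csv(path, dtype={"region_id": str}, float_precision="round_trip")
    return validate_frame(df, kind)


def write_frame(df: pd.DataFrame, path, kind: TableKind | str) -> None:
    """Validate *df* and write it as CSV with the documented column order.

    Floats are written at full repr precision, so a read_frame round-trip
    reproduces the values exactly.
    """
    kind = _as_kind(kind)
    df = validate_frame(df, kind)
    df.to_csv(path, index=False, columns=list(COLUMNS[kind]))


def adult_sex_ratio(
    pop: pd.DataFrame,
    region_id: str,
    year: int,
    male_ages: Sequence[int] = (20, 39),
    female_ages: Sequence[int] = (20, 39),
) -> float:
    """Male/female population ratio over inclusive age ranges.

    Returns sum of male counts over ``male_ages`` divided by the sum of
    female counts over ``female_ages``, both ranges inclusive of their
    endpoints in completed years. This is the reproductive-age sex ratio SR
    used as the regressor in the male-TFR regression; the age-gap model
    variant pairs men 25–44 with women 20–39.
    """
    sums = {}
    sub = pop[(pop["region_id"] == str(region_id)) & (pop["year"] == int(year))]
    for sex, (lo, hi) in (("male", tuple(male_ages)), ("female", tuple(female_ages))):
        if hi < lo:
            raise DomainError(f"{sex} age range ({lo}, {hi}) is empty")
        rows = sub[(sub["sex"] == sex) & sub["age"].between(lo, hi)]
        missing = sorted(set(range(lo, hi + 1)) - set(rows["age"]))
        if missing:
            raise MissingDataError(
                f"population for ({region_id}, {year}, {sex}) is missing ages {missing}"
            )
        sums[sex] = float(rows["count"].sum())
    if sums["female"] <= 0:
        raise DomainError(f"female population for ({region_id}, {year}) is zero")
    return sums["male"] / sums["female"]
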