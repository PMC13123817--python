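"""Demographic standardization: the male TFR under the female birth schedule.

The standardized TFR applies the observed births by maternal age to the
male population structure,

    TFR_std = sum_{x=15}^{55} B_x / P_x^male,

i.e. the TFR men would exhibit if they had children at exactly the ages
mothers do. Comparing it with the female TFR (sum of B_x / P_x^female over
the same ages) isolates the pure effect of reproductive-age sex ratios on
fertility differences, removing the age gap between parents by assumption.
The identical-schedule assumption is a deliberate simplification: real male
fertility schedules are shifted to older ages and broader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DomainError

__all__ = ["StandardizedTFR", "standardize", "standardize_panel", "split_grouped_births"]

DEFAULT_AGE_RANGE = (15, 55)


@dataclass
class StandardizedTFR:
    region_id: str
    year: int
    tfr_std: float       # births per man under the female schedule
    tfr_female: float    # births per woman from the same inputs
    ratio_std: float | None  # tfr_std / tfr_female, None when tfr_female == 0


def _births_by_mother_age(births: pd.DataFrame, region_id: str, year: int) -> pd.Series:
    sub = births[(births["region_id"] == str(region_id)) & (births["year"] == int(year))]
    sub = sub[sub["mother_age"] != "all"]
    # sum over sex_of_child, but never double count an 'all' marginal
    if (sub["sex_of_child"] == "all").any() and (sub["sex_of_child"] != "all").any():
        sub = sub[sub["sex_of_child"] != "all"]
    return sub.groupby("mother_age")["count"].sum()


def standardize(
    births: pd.DataFrame,
    pop: pd.DataFrame,
    region_id: str,
    year: int,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
) -> StandardizedTFR:
    """Standardized male TFR for one region-year.

    Ages where births and population are both zero contribute nothing; a
    positive birth count at an age with zero male population has no defined
    rate and raises :class:`DomainError` naming the age.
    """
    lo, hi = age_range
    bx = _births_by_mother_age(births, region_id, year)
    bx = bx[(bx.index >= lo) & (bx.index <= hi)]

    sub = pop[(pop["region_id"] == str(region_id)) & (pop["year"] == int(year))]
    sub = sub[sub["age"].between(lo, hi)]
    pop_by = {
        sex: sub[sub["sex"] == sex].groupby("age")["count"].sum() for sex in ("male", "female")
    }

    tfr = {}
    for sex in ("male", "female"):
        total = 0.0
        for age, b in bx.items():
            p = float(pop_by[sex].get(age, 0.0))
            if p <= 0.0:
                if b > 0.0:
                    raise DomainError(
                        f"births at mother_age {age} but zero {sex} population "
                        f"for ({region_id}, {year})"
                    )
                continue
            total += float(b) / p
        tfr[sex] = total

    ratio = tfr["male"] / tfr["female"] if tfr["female"] > 0 else None
    return StandardizedTFR(
        region_id=str(region_id),
        year=int(year),
        tfr_std=tfr["male"],
        tfr_female=tfr["female"],
        ratio_std=ratio,
    )


def standardize_panel(
    births: pd.DataFrame,
    pop: pd.DataFrame,
    regions=None,
    years=None,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
) -> tuple[pd.DataFrame, list[dict]]:
    """Vectorized :func:`standardize` over region-years present in *births*.

    Returns ``(table, skipped)`` where the table has columns region_id, year,
    tfr_std, tfr_female, ratio_std and skipped lists region-years that could
    not be standardized, with reasons.
    """
    keys = births[["region_id", "year"]].drop_duplicates()
    if regions is not None:
        keys = keys[keys["region_id"].isin([str(r) for r in regions])]
    if years is not None:
        keys = keys[keys["year"].isin([int(y) for y in years])]
    rows, skipped = [], []
    for rec in keys.itertuples(index=False):
        try:
            s = standardize(births, pop, rec.region_id, rec.year, age_range)
        except DomainError as e:
            skipped.append({"region_id": rec.region_id, "year": rec.year, "reason": str(e)})
            continue
        rows.append(
            {
                "region_id": s.region_id,
                "year": s.year,
                "tfr_std": s.tfr_std,
                "tfr_female": s.tfr_female,
                "ratio_std": np.nan if s.ratio_std is None else s.ratio_std,
            }
        )
    return pd.DataFrame(rows), skipped


def split_grouped_births(births: pd.DataFrame, width: int = 5) -> pd.DataFrame:
    """Split births reported in *width*-year maternal age groups into single ages.

    Each non-``"all"`` row is taken to start its group at ``mother_age`` and
    is split uniformly over ``mother_age .. mother_age + width - 1``. Totals
    are preserved exactly. Useful for sources that publish 5-year groups.
    """
    rows = []
    for rec in births.itertuples(index=False):
        d = rec._asdict()
        if d["mother_age"] == "all":
            rows.append(d)
            continue
        for offset in range(width):
            split = dict(d)
            split["mother_age"] = int(d["mother_age"]) + offset
            split["count"] = d["count"] / width
            rows.append(split)
    return pd.DataFrame(rows, columns=births.columns)
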