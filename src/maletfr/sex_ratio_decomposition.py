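"""Synthetic-cohort decomposition of age-specific population sex ratios.

Starting a hypothetical cohort with the observed sex ratio at birth (radix
SRB men per 100 women) and subjecting it to one calendar year's sex-specific
period life tables yields, at each age x,

    SR_t(x) = 100 * (B_m / B_w)                      [birth contribution]
              * prod_{i=0}^{x-1} p_m(i) / p_w(i)     [mortality contribution]

— the number of men per 100 women at age x implied by that year's birth and
mortality regime alone, with migration excluded by construction. The
survivorship product runs from birth to *exact* age x, so the empty product
at x = 0 makes SR_t(0) equal the sex ratio at birth, consistent with the
radix convention. The two factors multiply to the total exactly, which is
the decomposition's defining identity.

Because period rates of a single year t are used at all ages (a synthetic
cohort, not a real one), SR_t(x) is a counterfactual: the sex composition a
population would converge to if year t's rates persisted. Under actually
time-constant rates and no migration it coincides with the observed
population sex ratio at every age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import DomainError, MissingDataError

__all__ = ["decompose", "crossover_age", "plot_decomposition"]


def _births_by_sex(births: pd.DataFrame, region_id: str, year: int) -> dict[str, float]:
    sub = births[(births["region_id"] == str(region_id)) & (births["year"] == int(year))]
    out = {}
    for sex in ("male", "female"):
        rows = sub[sub["sex_of_child"] == sex]
        # prefer single-age rows; fall back to an 'all' marginal
        by_age = rows[rows["mother_age"] != "all"]
        out[sex] = float((by_age if len(by_age) else rows)["count"].sum())
    return out


def _survival_vector(
    lifetables: pd.DataFrame, region_id: str, year: int, sex: str, max_age: int
) -> np.ndarray:
    sub = lifetables[
        (lifetables["region_id"] == str(region_id))
        & (lifetables["year"] == int(year))
        & (lifetables["sex"] == sex)
    ]
    series = sub.set_index("age")["p"]
    missing = sorted(set(range(max_age)) - set(series.index))
    if missing:
        raise MissingDataError(
            f"life table for ({region_id}, {year}, {sex}) is missing ages {missing}"
        )
    return series.reindex(range(max_age)).to_numpy(dtype=float)


def decompose(
    births: pd.DataFrame,
    lifetables: pd.DataFrame,
    region_id: str,
    year: int,
    max_age: int = 100,
    scale: float = 100.0,
) -> pd.DataFrame:
    """Decompose the synthetic-cohort sex ratio at ages 0..max_age.

    Returns a frame with columns region_id, year, age, sr_total,
    birth_contribution, mortality_contribution, survival_ratio_increment.
    ``sr_total`` is men per ``scale`` women (default 100);
    ``birth_contribution`` is ``scale * Bm / Bw``; ``mortality_contribution``
    is the unitless cumulative survivorship ratio, identically 1 when male
    and female survival coincide. ``survival_ratio_increment`` is the
    single-age ratio ``p_m(x) / p_w(x)`` (NaN at the last age if the table
    stops there), provided so the per-age increments of the mortality factor
    can be plotted as well as the cumulative factor.
    """
    b = _births_by_sex(births, region_id, year)
    if b["female"] <= 0:
        raise DomainError(f"zero female births for ({region_id}, {year})")
    birth_contribution = scale * b["male"] / b["female"]

    pm = _survival_vector(lifetables, region_id, year, "male", max_age)
    pw = _survival_vector(lifetables, region_id, year, "female", max_age)
    ages = np.arange(max_age + 1)
    # survivorship from birth to exact age x: empty product at x = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mortality = np.concatenate([[1.0], np.cumprod(pm / pw)])
        increment = np.concatenate([pm / pw, [np.nan]])

    return pd.DataFrame(
        {
            "region_id": str(region_id),
            "year": int(year),
            "age": ages,
            "sr_total": birth_contribution * mortality,
            "birth_contribution": birth_contribution,
            "mortality_contribution": mortality,
            "survival_ratio_increment": increment,
        }
    )


def crossover_age(decomposition: pd.DataFrame, scale: float = 100.0) -> int | None:
    """Smallest age at which women outnumber men (sr_total strictly below parity).

    ``scale`` must match the scale the decomposition was computed on. Returns
    ``None`` if men are never outnumbered; exact parity does not count.
    """
    d = decomposition.sort_values("age")
    ages = d["age"].to_numpy()
    if len(ages) and not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
        raise DomainError("decomposition must cover contiguous ages")
    below = d[d["sr_total"] < scale]
    return int(below["age"].iloc[0]) if len(below) else None


def plot_decomposition(decomposition: pd.DataFrame, ax=None, scale: float = 100.0):
    """Bar-and-line chart: birth and mortality contributions vs total ratio."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = decomposition.sort_values("age")
    ax.bar(d["age"] - 0.2, d["birth_contribution"] / scale, width=0.4,
           color="purple", alpha=0.6, label="birth contribution")
    ax.bar(d["age"] + 0.2, d["mortality_contribution"], width=0.4,
           color="green", alpha=0.6, label="mortality contribution")
    ax.plot(d["age"], d["sr_total"] / scale, "k.-", label="population sex ratio")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("age")
    ax.set_ylabel("men per woman (ratio scale)")
    ax.legend()
    return ax
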