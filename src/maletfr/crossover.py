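"""Trend analytics over male and female TFR series.

Covers the descriptive layer of the analysis: per-year percent differences
between male and female TFR, detection of the crossover year (the first year
female fertility exceeds male fertility), cross-country shares by sign of
the gap, population-weighted shares of the world living under a substantial
(> 5%) male-fertility deficit, and an exact log-scale counterfactual
decomposition of TFR-ratio change into its female-TFR and sex-ratio drivers.

Boundary conventions: crossover requires *strictly* lower male TFR (ties do
not cross), and the 5% threshold is strict (a percent difference of exactly
-5 does not count as "more than 5% lower").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DomainError
from .male_tfr import RegressionFit

__all__ = [
    "CrossoverResult",
    "ShareSummary",
    "percent_difference",
    "detect_crossover",
    "crossover_result",
    "pi_indistinguishable_years",
    "share_summary",
    "counterfactual_ratio_decomposition",
    "plot_percent_difference",
]

PCT_DIFF_THRESHOLD = -5.0  # "more than 5% lower male TFR", strict


@dataclass
class CrossoverResult:
    region_id: str
    pct_diff_series: pd.Series        # per-year 100*(TFRm - TFRw)/TFRw, year index
    crossover_year: int | None        # first year TFRm < TFRw, strictly
    min_pct_diff_year: int            # year at which the series is lowest


@dataclass
class ShareSummary:
    year: int
    share_higher_male: float          # fraction of regions with TFRm > TFRw
    popshare_below_minus5: float      # population-weighted share with pct_diff < -5


def percent_difference(tfr_male: float, tfr_female: float):
    """100 * (TFRm - TFRw) / TFRw; positive when men's TFR is higher.

    Accepts scalars or aligned arrays; the female TFR must be positive.
    """
    tfr_female = np.asarray(tfr_female, dtype=float)
    if np.any(tfr_female <= 0):
        raise DomainError("tfr_female must be strictly positive")
    out = 100.0 * (np.asarray(tfr_male, dtype=float) - tfr_female) / tfr_female
    return float(out) if out.ndim == 0 else out


def _check_years(years: np.ndarray) -> None:
    if len(years) == 0:
        raise DomainError("series is empty")
    if not np.array_equal(years, np.arange(years[0], years[0] + len(years))):
        raise DomainError("years must be strictly increasing with no gaps")


def detect_crossover(series: pd.DataFrame) -> int | None:
    """First year with tfr_male strictly below tfr_female, or None.

    *series* needs columns year, tfr_male, tfr_female with consecutive
    years. Exact ties are "not crossed".
    """
    years = series["year"].to_numpy()
    _check_years(years)
    below = series["tfr_male"].to_numpy() < series["tfr_female"].to_numpy()
    idx = np.flatnonzero(below)
    return int(years[idx[0]]) if len(idx) else None


def crossover_result(region_id: str, series: pd.DataFrame) -> CrossoverResult:
    """Percent-difference series, crossover year, and minimum year for one region."""
    series = series.sort_values("year")
    pct = pd.Series(
        percent_difference(series["tfr_male"].to_numpy(), series["tfr_female"].to_numpy()),
        index=series["year"].to_numpy(),
        name="pct_diff",
    )
    return CrossoverResult(
        region_id=str(region_id),
        pct_diff_series=pct,
        crossover_year=detect_crossover(series),
        min_pct_diff_year=int(pct.idxmin()),
    )


def pi_indistinguishable_years(series: pd.DataFrame) -> list[int]:
    """Years where the male-TFR prediction interval straddles the female TFR.

    In such years the sign of the fertility gap is statistically
    indistinguishable from zero at the interval's level; crossovers detected
    there should be read with caution. Requires columns tfr_male_pi_low,
    tfr_male_pi_high.
    """
    mask = (series["tfr_male_pi_low"] < series["tfr_female"]) & (
        series["tfr_female"] < series["tfr_male_pi_high"]
    )
    return [int(y) for y in series.loc[mask, "year"]]


def share_summary(
    panel: pd.DataFrame,
    pop_totals: pd.DataFrame,
    threshold: float = PCT_DIFF_THRESHOLD,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-year shares of regions (and population) by sign and size of the gap.

    *panel* needs columns region_id, year, tfr_male, tfr_female;
    *pop_totals* needs region_id, year, population (total persons, all ages
    and sexes). Returns ``(summaries, skipped)``: summaries has columns
    year, share_higher_male, popshare_below_minus5; region-years lacking a
    population weight are excluded from the weighted share and reported in
    ``skipped``.
    """
    merged = panel.merge(pop_totals, on=["region_id", "year"], how="left")
    merged["pct_diff"] = percent_difference(
        merged["tfr_male"].to_numpy(), merged["tfr_female"].to_numpy()
    )
    skipped = [
        {"region_id": r.region_id, "year": int(r.year), "reason": "missing population weight"}
        for r in merged[merged["population"].isna()].itertuples(index=False)
    ]
    rows = []
    for year, grp in merged.groupby("year"):
        share_higher = float((grp["tfr_male"] > grp["tfr_female"]).mean())
        weighted = grp.dropna(subset=["population"])
        wtot = weighted["population"].sum()
        popshare = (
            float(weighted.loc[weighted["pct_diff"] < threshold, "population"].sum() / wtot)
            if wtot > 0
            else np.nan
        )
        rows.append(
            {"year": int(year), "share_higher_male": share_higher, "popshare_below_minus5": popshare}
        )
    return pd.DataFrame(rows), skipped


def counterfactual_ratio_decomposition(
    fit: RegressionFit | tuple,
    tfrw_0: float,
    sr_0: float,
    tfrw_1: float,
    sr_1: float,
) -> tuple[float, float, float]:
    """Exact decomposition of the change in log(TFRm/TFRw) between two states.

    Under the log-log model, log(TFRm/TFRw) = alpha + (beta_tfr - 1) log TFRw
    + beta_sr log SR, so the change between (tfrw_0, sr_0) and (tfrw_1, sr_1)
    splits additively into a fertility-level component and a sex-ratio
    component:

        total = (beta_tfr - 1) * (log tfrw_1 - log tfrw_0)
                + beta_sr * (log sr_1 - log sr_0)

    Returns ``(total, tfrw_component, sr_component)``; the components sum to
    the total exactly and the split is order-independent.
    """
    if min(tfrw_0, sr_0, tfrw_1, sr_1) <= 0:
        raise DomainError("all TFR and sex-ratio values must be strictly positive")
    if isinstance(fit, RegressionFit):
        _, beta_tfr, beta_sr = fit.coefficients
    else:
        _, beta_tfr, beta_sr = (float(c) for c in fit)
    tfrw_component = (beta_tfr - 1.0) * (np.log(tfrw_1) - np.log(tfrw_0))
    sr_component = beta_sr * (np.log(sr_1) - np.log(sr_0))
    return (tfrw_component + sr_component, float(tfrw_component), float(sr_component))


def plot_percent_difference(results: list[CrossoverResult], ax=None):
    """Line chart of percent differences with crossover years marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for r in results:
        (line,) = ax.plot(r.pct_diff_series.index, r.pct_diff_series.values, label=r.region_id)
        if r.crossover_year is not None:
            ax.axvline(r.crossover_year, color=line.get_color(), ls="--", lw=0.8)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("percent difference, male vs female TFR")
    ax.legend()
    return ax
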