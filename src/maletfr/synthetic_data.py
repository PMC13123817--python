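"""Synthetic WPP-like data with known ground truth.

A migration-free cohort-component projection produces the four input tables
(population, births, life tables, fertility) that the downstream stages
consume, internally consistent by construction:

* ``P(age+1, year+1, sex) = P(age, year, sex) * p(age, year, sex)`` exactly
  (the population balancing equation with zero migration);
* births by maternal age equal ``ASFR(age, year) * female P(age, year)``;
* male births / female births equal ``SRB(year) / 100``;
* the emitted life tables are exactly the survival probabilities used.

Counts are expected values (no Poisson noise), so every accounting identity
holds to machine precision and parameter-recovery tests have exact targets.

Mortality follows a Gompertz senescent hazard with a multiplicative
male/female gap plus optional additive infant and young-adult components;
fertility follows a two-parameter beta-shaped age schedule over ages 15-55
scaled to the year's TFR. Transient hazard shocks (conflict or maternal
mortality episodes) multiply the hazard of one sex over a year x age window.

The top age is closed at 100 (survival out of age 100 is zero), so cohorts
are extinguished rather than accumulated into an open interval and the
balancing identity holds at every emitted age.

The module also provides :func:`generate_regression_panel`, which draws
observations directly from the log-log male-TFR model for regression
parameter-recovery and interval-coverage tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import TableKind, validate_frame

__all__ = [
    "ConfigError",
    "MortalityParams",
    "FertilitySchedule",
    "Shock",
    "ScenarioConfig",
    "GroundTruth",
    "ScenarioData",
    "generate_scenario",
    "generate_regression_panel",
]


class ConfigError(ValueError):
    """A scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class MortalityParams:
    """Parametric per-sex hazard.

    Female hazard at completed age x:

        h_f(x) = gompertz_level * exp(gompertz_slope * x)
                 + infant_level * exp(-infant_decay * x)
                 + young_adult_level * exp(-((x - young_adult_age)^2
                                             / (2 * young_adult_spread^2)))

    The male hazard is ``sex_gap * h_f(x)``. Survival probabilities are
    ``p(x) = exp(-h(x))``. Defaults give a female life expectancy near 80
    with a typical male disadvantage.
    """

    gompertz_level: float = 5e-5
    gompertz_slope: float = 0.1
    sex_gap: float = 1.4
    infant_level: float = 0.015
    infant_decay: float = 1.2
    young_adult_level: float = 0.0
    young_adult_age: float = 22.0
    young_adult_spread: float = 6.0

    def hazard(self, ages: np.ndarray, sex: str) -> np.ndarray:
        h = self.gompertz_level * np.exp(self.gompertz_slope * ages)
        h = h + self.infant_level * np.exp(-self.infant_decay * ages)
        if self.young_adult_level:
            h = h + self.young_adult_level * np.exp(
                -((ages - self.young_adult_age) ** 2) / (2.0 * self.young_adult_spread**2)
            )
        if sex == "male":
            h = self.sex_gap * h
        return h


@dataclass(frozen=True)
class FertilitySchedule:
    """Beta-shaped age pattern of fertility over [age_min, age_max].

    Two parameters (mean and standard deviation of the age at childbearing)
    are mapped to beta shape parameters by the method of moments; the
    density is evaluated at age mid-points and normalized so the weights sum
    to one, then scaled by the year's TFR to give age-specific rates.
    """

    mean_age: float = 28.0
    sd_age: float = 6.0
    age_min: int = 15
    age_max: int = 55

    def weights(self) -> np.ndarray:
        span = self.age_max + 1 - self.age_min
        m = (self.mean_age - self.age_min) / span
        v = (self.sd_age / span) ** 2
        if not 0 < m < 1:
            raise ConfigError("mean_age must lie inside the schedule's age range")
        k = m * (1 - m) / v - 1
        if k <= 0:
            raise ConfigError("sd_age too large for a unimodal schedule on this range")
        ages = np.arange(self.age_min, self.age_max + 1)
        u = (ages + 0.5 - self.age_min) / span
        w = stats.beta.pdf(u, m * k, (1 - m) * k)
        return w / w.sum()


@dataclass(frozen=True)
class Shock:
    """Multiply the hazard of one sex by a factor over a year x age window.

    ``sex`` is "male", "female", or "both"; year and age bounds are
    inclusive; ``hazard_multiplier`` must be positive (values > 1 model
    conflict or maternal-mortality excess, values < 1 a mortality dividend).
    """

    year_start: int
    year_end: int
    sex: str
    age_start: int
    age_end: int
    hazard_multiplier: float


def _per_year(value, years: np.ndarray, name: str) -> np.ndarray:
    """Broadcast a scalar / sequence / {year: value} mapping onto *years*."""
    if isinstance(value, Mapping):
        try:
            return np.array([float(value[int(y)]) for y in years])
        except KeyError as e:
            raise ConfigError(f"{name} mapping is missing year {e.args[0]}")
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(len(years), arr[0])
    if arr.size != len(years):
        raise ConfigError(f"{name} has {arr.size} values for {len(years)} years")
    return arr


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic demographic scenario.

    ``srb`` is the sex ratio at birth in male births per 100 female births
    (naturally 103-107; larger under sex-selective abortion); ``tfr`` is the
    female total fertility rate. Both accept a scalar, a per-year sequence,
    or a {year: value} mapping. ``radix`` sets the female birth cohort size
    used to seed the initial (stationary-shape) population.
    """

    region_id: str = "SYN"
    start_year: int = 2000
    end_year: int = 2050
    srb: object = 105.0
    tfr: object = 2.1
    fertility_schedule: FertilitySchedule = field(default_factory=FertilitySchedule)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    shocks: Sequence[Shock] = ()
    seed: int = 0
    max_age: int = 100
    radix: float = 100_000.0

    def validate(self) -> None:
        if self.end_year < self.start_year:
            raise ConfigError("end_year must not precede start_year")
        years = self.years()
        if np.any(_per_year(self.srb, years, "srb") <= 0):
            raise ConfigError("srb values must be positive")
        if np.any(_per_year(self.tfr, years, "tfr") < 0):
            raise ConfigError("tfr values must be non-negative")
        for s in self.shocks:
            if s.hazard_multiplier <= 0:
                raise ConfigError("shock hazard multipliers must be positive")
            if s.sex not in ("male", "female", "both"):
                raise ConfigError(f"shock sex {s.sex!r} must be male/female/both")

    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "fertility_schedule" in d and isinstance(d["fertility_schedule"], Mapping):
            d["fertility_schedule"] = FertilitySchedule(**d["fertility_schedule"])
        if "mortality" in d and isinstance(d["mortality"], Mapping):
            d["mortality"] = MortalityParams(**d["mortality"])
        if "shocks" in d:
            d["shocks"] = tuple(
                Shock(**s) if isinstance(s, Mapping) else s for s in d["shocks"]
            )
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized generating quantities, for parameter-recovery tests.

    ``survival`` has columns (year, sex, age, p); ``asfr`` has columns
    (year, age, rate); ``srb`` and ``tfr_female`` map year to the realized
    sex ratio at birth and female TFR.
    """

    srb: dict
    tfr_female: dict
    asfr: pd.DataFrame
    survival: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "srb": {str(k): v for k, v in self.srb.items()},
            "tfr_female": {str(k): v for k, v in self.tfr_female.items()},
            "asfr": self.asfr.to_dict(orient="list"),
            "survival": self.survival.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class ScenarioData(NamedTuple):
    population: pd.DataFrame
    births: pd.DataFrame
    lifetable: pd.DataFrame
    fertility: pd.DataFrame
    ground_truth: GroundTruth


def _survival_grid(config: ScenarioConfig) -> dict[str, np.ndarray]:
    """p(age, year, sex) including shocks; shape (n_years, max_age+1).

    Survival out of the top age is forced to zero (closed top interval).
    """
    ages = np.arange(config.max_age + 1)
    years = config.years()
    out = {}
    for sex in ("male", "female"):
        base = config.mortality.hazard(ages.astype(float), sex)
        hazard = np.tile(base, (len(years), 1))
        for s in config.shocks:
            if s.sex not in (sex, "both"):
                continue
            yr = (years >= s.year_start) & (years <= s.year_end)
            ag = (ages >= s.age_start) & (ages <= s.age_end)
            hazard[np.ix_(yr, ag)] *= s.hazard_multiplier
        p = np.exp(-hazard)
        p[:, config.max_age] = 0.0
        out[sex] = p
    return out


def generate_scenario(config: ScenarioConfig) -> ScenarioData:
    """Run the deterministic no-migration cohort-component projection.

    The initial population has the stationary shape implied by the first
    year's rates: female counts ``radix * l_f(x)`` and male counts
    ``radix * (SRB/100) * l_m(x)``, where ``l(x)`` is cumulative
    survivorship from birth. Because every cohort — seeded or born during
    the projection — then carries the sex ratio ``(SRB/100) * l_m/l_f`` of
    its birth year's regime, time-constant rates make the period population
    sex ratio at each age coincide exactly with the synthetic-cohort
    decomposition.
    """
    config.validate()
    years = config.years()
    n_years = len(years)
    ages = np.arange(config.max_age + 1)
    srb = _per_year(config.srb, years, "srb")
    tfr = _per_year(config.tfr, years, "tfr")
    p = _survival_grid(config)
    weights = config.fertility_schedule.weights()
    fert_ages = np.arange(config.fertility_schedule.age_min, config.fertility_schedule.age_max + 1)
    asfr = np.outer(tfr, weights)  # (year, fertile age)

    pop = {s: np.zeros((n_years, config.max_age + 1)) for s in ("male", "female")}
    for sex, scale in (("female", 1.0), ("male", srb[0] / 100.0)):
        survivorship = np.concatenate([[1.0], np.cumprod(p[sex][0, :-1])])
        pop[sex][0] = config.radix * scale * survivorship

    births_m = np.zeros((n_years, len(fert_ages)))
    births_f = np.zeros((n_years, len(fert_ages)))
    for t in range(n_years):
        total = asfr[t] * pop["female"][t, fert_ages]
        births_f[t] = total * 100.0 / (100.0 + srb[t])
        births_m[t] = total * srb[t] / (100.0 + srb[t])
        if t + 1 < n_years:
            for sex, newborn in (("female", births_f[t]), ("male", births_m[t])):
                pop[sex][t + 1, 1:] = pop[sex][t, :-1] * p[sex][t, :-1]
                pop[sex][t + 1, 0] = newborn.sum()

    pop_df = pd.DataFrame(
        {
            "region_id": config.region_id,
            "year": np.repeat(years, 2 * len(ages)),
            "age": np.tile(np.concatenate([ages, ages]), n_years),
            "sex": np.tile(["male"] * len(ages) + ["female"] * len(ages), n_years),
            "count": np.concatenate(
                [np.concatenate([pop["male"][t], pop["female"][t]]) for t in range(n_years)]
            ),
        }
    )
    births_df = pd.DataFrame(
        {
            "region_id": config.region_id,
            "year": np.repeat(years, 2 * len(fert_ages)),
            "sex_of_child": np.tile(
                ["male"] * len(fert_ages) + ["female"] * len(fert_ages), n_years
            ),
            "mother_age": np.tile(np.concatenate([fert_ages, fert_ages]), n_years),
            "count": np.concatenate(
                [np.concatenate([births_m[t], births_f[t]]) for t in range(n_years)]
            ),
        }
    )
    lt_df = pd.DataFrame(
        {
            "region_id": config.region_id,
            "year": np.repeat(years, 2 * len(ages)),
            "sex": np.tile(["male"] * len(ages) + ["female"] * len(ages), n_years),
            "age": np.tile(np.concatenate([ages, ages]), n_years),
            "p": np.concatenate(
                [np.concatenate([p["male"][t], p["female"][t]]) for t in range(n_years)]
            ),
        }
    )
    fert_df = pd.DataFrame(
        {
            "region_id": config.region_id,
            "year": years,
            "tfr_female": asfr.sum(axis=1),
            "tfr_male": np.nan,
        }
    )

    truth = GroundTruth(
        srb={int(y): float(s) for y, s in zip(years, srb)},
        tfr_female={int(y): float(v) for y, v in zip(years, asfr.sum(axis=1))},
        asfr=pd.DataFrame(
            {
                "year": np.repeat(years, len(fert_ages)),
                "age": np.tile(fert_ages, n_years),
                "rate": asfr.ravel(),
            }
        ),
        survival=lt_df[["year", "sex", "age", "p"]].copy(),
    )
    return ScenarioData(
        population=validate_frame(pop_df, TableKind.POPULATION),
        births=validate_frame(births_df, TableKind.BIRTHS),
        lifetable=validate_frame(lt_df, TableKind.LIFETABLE),
        fertility=validate_frame(fert_df, TableKind.FERTILITY),
        ground_truth=truth,
    )


def generate_regression_panel(
    n: int,
    coefficients: Sequence[float] = (-0.078, 1.101, -0.661),
    noise_sd: float = 0.05,
    log_tfrw_range: tuple[float, float] = (np.log(0.8), np.log(8.0)),
    log_sr_dist: tuple[float, float] = (0.0, 0.15),
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw (tfr_female, sex_ratio, tfr_male) observations from the log-log model.

    log TFRm = alpha + beta_tfr * log TFRw + beta_sr * log SR + N(0, noise_sd^2),
    with log TFRw uniform on ``log_tfrw_range`` and log SR normal with the
    mean/sd in ``log_sr_dist``. Deterministic given ``seed``.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    alpha, beta_tfr, beta_sr = (float(c) for c in coefficients)
    rng = np.random.default_rng(seed)
    log_tfrw = rng.uniform(*log_tfrw_range, size=n)
    log_sr = rng.normal(log_sr_dist[0], log_sr_dist[1], size=n)
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    log_tfrm = alpha + beta_tfr * log_tfrw + beta_sr * log_sr + eps
    return pd.DataFrame(
        {
            "tfr_female": np.exp(log_tfrw),
            "sex_ratio": np.exp(log_sr),
            "tfr_male": np.exp(log_tfrm),
        }
    )
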