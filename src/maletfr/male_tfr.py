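"""Regression-based estimation of the male total fertility rate.

Male TFRs are rarely published, but they are tightly linked to the female
TFR and to the sex composition of the reproductive-age population: with more
men per woman, the same births are spread over more male person-years and
the male TFR falls. The model is a log-log OLS elasticity regression

    log TFRm = alpha + beta_tfr * log TFRw + beta_sr * log SR + eps,

where SR is the reproductive-age sex ratio. Three variants differ only in
the age ranges defining SR:

* ``baseline``      — men 20-39 / women 20-39;
* ``postponement``  — men 25-44 / women 25-44 (shifted for fertility
  postponement);
* ``age_gap``       — men 25-44 / women 20-39, reflecting that fathers are
  typically older than mothers at childbirth. This variant fits best in
  published global applications and is the package default.

Prediction intervals are normal-theory OLS intervals on the log scale
(t distribution with n-3 degrees of freedom, prediction variance
x'Vx + resid_sd^2), exponentiated to the natural scale. When only point
coefficients are supplied (no covariance), intervals are unavailable and
``predict`` returns the point estimate alone.

``DEFAULT_COEFFICIENTS`` ships published reference estimates of the three
variants fitted on ~4,000 country-years of harmonized male-TFR data, usable
for prediction when no training data are at hand.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_data import DomainError, adult_sex_ratio

__all__ = [
    "ModelVariant",
    "VARIANTS",
    "DEFAULT_COEFFICIENTS",
    "SingularityError",
    "RegressionFit",
    "PredictionResult",
    "fit",
    "predict",
    "estimate_panel",
    "validate_out_of_sample",
]


class SingularityError(ValueError):
    """The regression design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelVariant:
    name: str
    male_ages: tuple[int, int]
    female_ages: tuple[int, int]


BASELINE = ModelVariant("baseline", (20, 39), (20, 39))
POSTPONEMENT = ModelVariant("postponement", (25, 44), (25, 44))
AGE_GAP = ModelVariant("age_gap", (25, 44), (20, 39))

VARIANTS = {v.name: v for v in (BASELINE, POSTPONEMENT, AGE_GAP)}

# Published reference coefficient sets (alpha, beta_tfr, beta_sr) per variant,
# from a global fit on n = 4,024 country-years; shipped as usable defaults.
DEFAULT_COEFFICIENTS = {
    "baseline": (-0.092, 1.182, -0.887),
    "postponement": (-0.114, 1.197, -0.849),
    "age_gap": (-0.078, 1.101, -0.661),
}


@dataclass
class RegressionFit:
    """OLS fit of the log-log male-TFR model."""

    variant: ModelVariant
    alpha: float
    beta_tfr: float
    beta_sr: float
    resid_sd: float
    n_obs: int
    r_squared: float
    adj_r_squared: float
    cov: np.ndarray  # 3x3 coefficient covariance, order (alpha, beta_tfr, beta_sr)

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta_tfr, self.beta_sr)

    def to_json(self, path) -> None:
        payload = {
            "variant": self.variant.name,
            "alpha": self.alpha,
            "beta_tfr": self.beta_tfr,
            "beta_sr": self.beta_sr,
            "resid_sd": self.resid_sd,
            "n_obs": self.n_obs,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "cov": np.asarray(self.cov).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RegressionFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            variant=VARIANTS[d["variant"]],
            alpha=d["alpha"],
            beta_tfr=d["beta_tfr"],
            beta_sr=d["beta_sr"],
            resid_sd=d["resid_sd"],
            n_obs=d["n_obs"],
            r_squared=d["r_squared"],
            adj_r_squared=d["adj_r_squared"],
            cov=np.asarray(d["cov"], dtype=float),
        )


@dataclass
class PredictionResult:
    """Point prediction (births per man) with optional 90% prediction bounds."""

    point: float
    pi_low: float | None
    pi_high: float | None
    log_point: float
    log_se: float | None


def _observation_arrays(observations) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(observations, pd.DataFrame):
        tm = observations["tfr_male"].to_numpy(dtype=float)
        tw = observations["tfr_female"].to_numpy(dtype=float)
        sr = observations["sex_ratio"].to_numpy(dtype=float)
    else:
        arr = np.asarray(observations, dtype=float)
        tm, tw, sr = arr[:, 0], arr[:, 1], arr[:, 2]
    return tm, tw, sr


def fit(observations, variant: ModelVariant | str = AGE_GAP) -> RegressionFit:
    """Pooled unweighted OLS on log-transformed observations.

    *observations* is a DataFrame with columns ``tfr_male``, ``tfr_female``,
    ``sex_ratio`` (or an (n, 3) array in that order). All values must be
    strictly positive. The residual standard deviation uses denominator
    n - 3 (the OLS error-variance estimate with three parameters).
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    tm, tw, sr = _observation_arrays(observations)
    n = len(tm)
    if n < 3:
        raise DomainError("need at least 3 observations to fit three coefficients")
    if np.any(tm <= 0) or np.any(tw <= 0) or np.any(sr <= 0):
        raise DomainError("all TFR and sex-ratio observations must be strictly positive")
    X = sm.add_constant(np.column_stack([np.log(tw), np.log(sr)]), has_constant="add")
    if np.linalg.matrix_rank(X) < 3:
        raise SingularityError("log TFRw and log SR are collinear; cannot identify the model")
    res = sm.OLS(np.log(tm), X).fit()
    return RegressionFit(
        variant=variant,
        alpha=float(res.params[0]),
        beta_tfr=float(res.params[1]),
        beta_sr=float(res.params[2]),
        resid_sd=float(np.sqrt(res.scale)),  # scale = SSR / (n - 3)
        n_obs=n,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        cov=np.asarray(res.cov_params()),
    )


def predict(
    fit_or_coefficients,
    tfr_female: float,
    sex_ratio: float,
    pi_level: float = 0.90,
) -> PredictionResult:
    """Predict the male TFR at given female TFR and reproductive-age sex ratio.

    With a :class:`RegressionFit` the result carries a prediction interval at
    ``pi_level``; with a bare (alpha, beta_tfr, beta_sr) coefficient sequence
    the interval is unavailable (no covariance or residual scale) and only
    the point estimate is returned.
    """
    if tfr_female <= 0 or sex_ratio <= 0:
        raise DomainError("tfr_female and sex_ratio must be strictly positive")
    if not 0 < pi_level < 1:
        raise DomainError("pi_level must lie in (0, 1)")
    x = np.array([1.0, math.log(tfr_female), math.log(sex_ratio)])
    if isinstance(fit_or_coefficients, RegressionFit):
        f = fit_or_coefficients
        log_point = float(x @ np.array(f.coefficients))
        pred_var = float(x @ f.cov @ x) + f.resid_sd**2
        log_se = math.sqrt(pred_var)
        t_crit = stats.t.ppf(0.5 + pi_level / 2.0, df=f.n_obs - 3)
        return PredictionResult(
            point=math.exp(log_point),
            pi_low=math.exp(log_point - t_crit * log_se),
            pi_high=math.exp(log_point + t_crit * log_se),
            log_point=log_point,
            log_se=log_se,
        )
    coefs = np.asarray(fit_or_coefficients, dtype=float)
    log_point = float(x @ coefs)
    return PredictionResult(
        point=math.exp(log_point), pi_low=None, pi_high=None, log_point=log_point, log_se=None
    )


def estimate_panel(
    pop: pd.DataFrame,
    fert: pd.DataFrame,
    fit: RegressionFit,
    pi_level: float = 0.90,
) -> tuple[pd.DataFrame, list[dict]]:
    """Fill ``tfr_male`` for every region-year of *fert* via the fitted model.

    For each region-year the variant's reproductive-age sex ratio is computed
    from the population table and fed to :func:`predict`. Region-years whose
    population is missing the needed ages (or whose female TFR is zero, where
    the log-log model is undefined) are skipped and reported, never dropped
    silently. Returns ``(estimates, skipped)``; estimates carry columns
    region_id, year, tfr_female, sex_ratio, tfr_male, tfr_male_pi_low,
    tfr_male_pi_high.
    """
    rows, skipped = [], []
    for rec in fert.itertuples(index=False):
        try:
            sr = adult_sex_ratio(
                pop, rec.region_id, rec.year, fit.variant.male_ages, fit.variant.female_ages
            )
            pr = predict(fit, rec.tfr_female, sr, pi_level)
        except (DomainError, ValueError) as e:
            skipped.append({"region_id": rec.region_id, "year": rec.year, "reason": str(e)})
            continue
        rows.append(
            {
                "region_id": rec.region_id,
                "year": rec.year,
                "tfr_female": rec.tfr_female,
                "sex_ratio": sr,
                "tfr_male": pr.point,
                "tfr_male_pi_low": pr.pi_low,
                "tfr_male_pi_high": pr.pi_high,
            }
        )
    return pd.DataFrame(rows), skipped


def validate_out_of_sample(
    fit: RegressionFit,
    holdout,
    pi_level: float = 0.90,
) -> tuple[float, float]:
    """Out-of-sample RMSE (log scale) and prediction-interval coverage.

    ``rmse = sqrt(mean((log observed - log predicted)^2))`` over the holdout
    observations; coverage is the share of observed male TFRs inside the
    ``pi_level`` prediction interval.
    """
    tm, tw, sr = _observation_arrays(holdout)
    if len(tm) == 0:
        raise DomainError("holdout set is empty")
    if np.any(tm <= 0) or np.any(tw <= 0) or np.any(sr <= 0):
        raise DomainError("holdout observations must be strictly positive")
    sq_err = np.empty(len(tm))
    inside = np.empty(len(tm), dtype=bool)
    for i in range(len(tm)):
        pr = predict(fit, tw[i], sr[i], pi_level)
        sq_err[i] = (math.log(tm[i]) - pr.log_point) ** 2
        inside[i] = pr.pi_low <= tm[i] <= pr.pi_high
    return float(np.sqrt(sq_err.mean())), float(inside.mean())
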