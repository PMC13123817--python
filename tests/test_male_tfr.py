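"""Log-log male-TFR regression: fitting, prediction, validation."""

import math

import numpy as np
import pandas as pd
import pytest

from maletfr import (
    AGE_GAP,
    DEFAULT_COEFFICIENTS,
    DomainError,
    SingularityError,
    estimate_panel,
    fit,
    generate_regression_panel,
    predict,
    validate_out_of_sample,
)

COEFS = DEFAULT_COEFFICIENTS["age_gap"]  # (-0.078, 1.101, -0.661)


class TestFit:
    def test_hand_solved_four_point_interpolation(self):
        """(TFRw, SR, TFRm) = (2,1,2),(4,1,4),(2,2,1),(4,2,2) satisfy
        log TFRm = log TFRw - log SR exactly, so OLS must interpolate with
        alpha=0, beta_tfr=1, beta_sr=-1 and zero residual.

        Independent oracle: solve the 4x3 normal equations with lstsq on
        hand-built logs, bypassing the fit path entirely.
        """
        obs = pd.DataFrame(
            {
                "tfr_male": [2.0, 4.0, 1.0, 2.0],
                "tfr_female": [2.0, 4.0, 2.0, 4.0],
                "sex_ratio": [1.0, 1.0, 2.0, 2.0],
            }
        )
        X = np.column_stack(
            [np.ones(4), np.log(obs.tfr_female), np.log(obs.sex_ratio)]
        )
        oracle, *_ = np.linalg.lstsq(X, np.log(obs.tfr_male), rcond=None)
        np.testing.assert_allclose(oracle, [0.0, 1.0, -1.0], atol=1e-12)

        f = fit(obs, AGE_GAP)
        assert f.alpha == pytest.approx(0.0, abs=1e-10)
        assert f.beta_tfr == pytest.approx(1.0, abs=1e-10)
        assert f.beta_sr == pytest.approx(-1.0, abs=1e-10)
        assert f.resid_sd == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_panel_recovers_coefficients_exactly(self):
        panel = generate_regression_panel(200, COEFS, noise_sd=0.0, seed=2)
        f = fit(panel)
        assert f.alpha == pytest.approx(COEFS[0], abs=1e-10)
        assert f.beta_tfr == pytest.approx(COEFS[1], abs=1e-10)
        assert f.beta_sr == pytest.approx(COEFS[2], abs=1e-10)
        assert f.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_ci_coverage_of_generating_slopes(self):
        """The fitted 95% CI covers the generating beta1 in >= 90% of
        seeded replications (binomial slack around the nominal 95%)."""
        hits = 0
        reps = 100
        for seed in range(reps):
            panel = generate_regression_panel(4000, COEFS, 0.05, seed=seed)
            f = fit(panel)
            se = math.sqrt(f.cov[1, 1])
            if abs(f.beta_tfr - COEFS[1]) <= 1.96 * se:
                hits += 1
        assert hits >= 0.90 * reps

    def test_covariance_symmetric_psd(self):
        f = fit(generate_regression_panel(500, COEFS, 0.05, seed=9))
        np.testing.assert_allclose(f.cov, f.cov.T, atol=1e-15)
        assert np.all(np.linalg.eigvalsh(f.cov) >= -1e-15)

    def test_nonpositive_observation_rejected(self):
        obs = pd.DataFrame(
            {"tfr_male": [2.0, -1.0, 1.0], "tfr_female": [2.0, 2.0, 2.0], "sex_ratio": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(DomainError):
            fit(obs)

    def test_collinear_design_rejected(self):
        obs = pd.DataFrame(
            {"tfr_male": [2.0, 3.0, 4.0], "tfr_female": [2.0, 3.0, 4.0], "sex_ratio": [2.0, 3.0, 4.0]}
        )
        with pytest.raises(SingularityError):
            fit(obs)


class TestPredict:
    @pytest.mark.parametrize(
        "tfrw, sr, expected, ndigits",
        [
            (2.1, 1.0, 2.09, 2),
            (2.1, 0.5, 3.31, 2),
            (2.1, 2.0, 1.32, 2),
            (1.0, 1.0, 0.92, 2),
            (3.0, 1.0, 3.1, 1),
        ],
    )
    def test_reference_coefficient_predictions(self, tfrw, sr, expected, ndigits):
        """The shipped age-gap coefficients reproduce the published worked
        predictions at their printed precision."""
        pr = predict(COEFS, tfrw, sr)
        assert round(pr.point, ndigits) == expected
        assert pr.pi_low is None and pr.pi_high is None  # no covariance supplied

    def test_unit_inputs_return_exp_alpha(self):
        pr = predict((0.3, 1.7, -0.4), 1.0, 1.0)
        assert pr.point == pytest.approx(math.exp(0.3), rel=1e-12)

    def test_monotone_in_tfrw_and_sr(self):
        f = fit(generate_regression_panel(1000, COEFS, 0.05, seed=4))
        assert f.beta_tfr > 0 > f.beta_sr
        p = [predict(f, tw, 1.0).point for tw in (1.0, 2.0, 3.0)]
        assert p[0] < p[1] < p[2]
        q = [predict(f, 2.0, sr).point for sr in (0.5, 1.0, 2.0)]
        assert q[0] > q[1] > q[2]

    def test_interval_brackets_point_and_is_positive(self):
        f = fit(generate_regression_panel(1000, COEFS, 0.05, seed=4))
        pr = predict(f, 2.1, 1.0)
        assert 0 < pr.pi_low <= pr.point <= pr.pi_high

    def test_pi_width_approaches_residual_only_asymptote(self):
        """As n grows the parameter variance vanishes and the log-scale PI
        half-width tends to t * resid_sd from above."""
        widths = {}
        for n in (100, 10000):
            f = fit(generate_regression_panel(n, COEFS, 0.05, seed=8))
            pr = predict(f, 2.1, 1.0)
            widths[n] = (math.log(pr.pi_high) - math.log(pr.pi_low)) / 2, f.resid_sd
        for n, (half, resid_sd) in widths.items():
            assert half > 1.6449 * resid_sd  # never narrower than the asymptote
        slack_small = widths[100][0] / widths[100][1]
        slack_big = widths[10000][0] / widths[10000][1]
        assert slack_big < slack_small  # shrinks toward the z-quantile

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            predict(COEFS, -1.0, 1.0)
        with pytest.raises(DomainError):
            predict(COEFS, 2.0, 0.0)


class TestEstimatePanel:
    def _fit(self):
        return fit(generate_regression_panel(2000, COEFS, 0.05, seed=6))

    def test_constant_inputs_give_constant_output(self, constant_scenario):
        """While the adult age windows hold only seeded cohorts (through
        2019 here: women born 1961-1999 fill ages 20-39) the sex ratio and
        female TFR are exactly constant, so the estimate must be too."""
        f = self._fit()
        est, skipped = estimate_panel(constant_scenario.population, constant_scenario.fertility, f)
        assert not skipped
        early = est[est.year <= 2020]
        np.testing.assert_allclose(early.sex_ratio, early.sex_ratio.iloc[0], rtol=1e-12)
        np.testing.assert_allclose(early.tfr_male, early.tfr_male.iloc[0], rtol=1e-12)
        late = est[est.year > 2020]  # in-sim cohorts age into the windows
        assert late.sex_ratio.iloc[-1] != pytest.approx(early.sex_ratio.iloc[0], rel=1e-6)
        direct = predict(f, early.tfr_female.iloc[0], early.sex_ratio.iloc[0]).point
        assert early.tfr_male.iloc[0] == pytest.approx(direct, rel=1e-12)

    def test_sex_ratio_doubling_shifts_log_tfr_by_beta_sr_ln2(self, constant_scenario):
        """Two regions differing only in SR: exact model linearity in logs."""
        f = self._fit()
        pop = constant_scenario.population
        doubled = pop.copy()
        doubled.loc[doubled.sex == "male", "count"] *= 2
        doubled["region_id"] = "R2"
        fert = constant_scenario.fertility
        fert2 = fert.copy()
        fert2["region_id"] = "R2"
        est, _ = estimate_panel(
            pd.concat([pop, doubled]), pd.concat([fert, fert2]), f
        )
        a = est[est.region_id == "SYN"].set_index("year").tfr_male
        b = est[est.region_id == "R2"].set_index("year").tfr_male
        np.testing.assert_allclose(np.log(b) - np.log(a), f.beta_sr * math.log(2), rtol=1e-9)

    def test_missing_population_reported_not_silent(self, constant_scenario):
        f = self._fit()
        fert = constant_scenario.fertility.copy()
        extra = fert.iloc[[0]].assign(region_id="GHOST")
        est, skipped = estimate_panel(
            constant_scenario.population, pd.concat([fert, extra]), f
        )
        assert len(skipped) == 1 and skipped[0]["region_id"] == "GHOST"
        assert set(est.region_id) == {"SYN"}

    def test_rising_srb_depresses_male_female_ratio(self):
        """With beta_sr < 0, a masculinizing population must lower TFRm/TFRw."""
        from maletfr import ScenarioConfig, generate_scenario

        years = list(range(2000, 2041))
        srb = {y: 105.0 + 0.5 * (y - 2000) for y in years}  # ramp 105 -> 125
        data = generate_scenario(ScenarioConfig(start_year=2000, end_year=2040, srb=srb))
        f = self._fit()
        est, _ = estimate_panel(data.population, data.fertility, f)
        ratio = (est.tfr_male / est.tfr_female).to_numpy()
        sr = est.sex_ratio.to_numpy()
        # the adult sex ratio rises with a lag; wherever it rises, the ratio falls
        rising = np.diff(sr) > 1e-12
        assert rising.any()
        assert np.all(np.diff(ratio)[rising] < 0)


class TestValidation:
    def test_noiseless_holdout_has_zero_rmse(self):
        panel = generate_regression_panel(500, COEFS, 0.05, seed=12)
        f = fit(panel)
        holdout = generate_regression_panel(200, f.coefficients, 0.0, seed=13)
        rmse, coverage = validate_out_of_sample(f, holdout)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert coverage == 1.0

    def test_known_noise_recovered_in_rmse(self):
        """Holdout generated with sd 0.05 from the fitted line: RMSE ~ 0.05."""
        panel = generate_regression_panel(4000, COEFS, 0.05, seed=14)
        f = fit(panel)
        holdout = generate_regression_panel(1000, f.coefficients, 0.05, seed=15)
        rmse, _ = validate_out_of_sample(f, holdout)
        # chi distribution: sd of RMSE ~ sigma/sqrt(2n) ~ 0.0011; allow 4 sd
        assert rmse == pytest.approx(0.05, abs=0.0045)

    def test_empty_holdout_rejected(self):
        f = fit(generate_regression_panel(100, COEFS, 0.05, seed=16))
        with pytest.raises(DomainError):
            validate_out_of_sample(f, pd.DataFrame(columns=["tfr_male", "tfr_female", "sex_ratio"]))
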