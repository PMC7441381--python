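"""Logistic estimators: fits, strata, interaction, curves, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from polypen import models


def _expand_2x2(a, b, c, d):
    """Individual-level data from a 2x2 (exposed-case etc.) table."""
    y = np.concatenate([np.ones(a), np.ones(c), np.zeros(b), np.zeros(d)])
    x = np.concatenate([np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)])
    return y, pd.DataFrame({"x": x})


class TestFitLogistic:
    def test_matches_closed_form_2x2(self):
        # carrier counts from a coronary disease case-control design:
        # 43 exposed cases, 13 exposed controls, 6389/6407 unexposed
        a, b, c, d = 43, 13, 6389, 6407
        y, X = _expand_2x2(a, b, c, d)
        fit = models.fit_logistic(y, X)
        assert fit.converged and not fit.separation
        expected = np.log(a * d / (b * c))
        assert fit.coefficients["x"] == pytest.approx(expected, abs=1e-6)
        or_v, lo, hi = models.two_by_two_or(a, b, c, d)
        assert np.log(or_v) == pytest.approx(expected, abs=1e-12)
        assert lo < or_v < hi

    def test_matches_statsmodels(self, rng):
        n = 800
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        eta = 0.3 + X @ [0.5, -0.8, 0.0]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        fit = models.fit_logistic(y.astype(float), X)
        sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), sm_fit.params.to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose(
            fit.covariance.to_numpy(), sm_fit.cov_params().to_numpy(), rtol=1e-4
        )

    def test_brute_force_likelihood_oracle_on_toy(self):
        # 20-row toy, 1 predictor: grid search the log-likelihood surface
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = (rng.random(20) < 1 / (1 + np.exp(-x))).astype(float)
        fit = models.fit_logistic(y, pd.DataFrame({"x": x}))
        b0 = np.linspace(-3, 3, 241)
        b1 = np.linspace(-3, 3, 241)
        ll = np.array(
            [
                [np.sum(y * (a + b * x) - np.logaddexp(0, a + b * x)) for b in b1]
                for a in b0
            ]
        )
        i, j = np.unravel_index(ll.argmax(), ll.shape)
        assert fit.coefficients["intercept"] == pytest.approx(b0[i], abs=0.05)
        assert fit.coefficients["x"] == pytest.approx(b1[j], abs=0.05)
        assert fit.loglik >= ll.max() - 1e-9

    def test_null_predictors_give_zero_slopes(self, rng):
        n = 2000
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = (rng.random(n) < 0.3).astype(float)
        fit = models.fit_logistic(y, X)
        assert abs(fit.coefficients["x"]) < 3 * fit.se["x"]

    def test_single_class_outcome_errors(self):
        with pytest.raises(ValueError, match="single class"):
            models.fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_separation_flagged(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = (x > 0).astype(float)
        fit = models.fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.separation

    def test_wald_ci_symmetric_on_log_scale(self, rng):
        n = 500
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = (rng.random(n) < 0.4).astype(float)
        fit = models.fit_logistic(y, X)
        or_v, lo, hi, _ = fit.wald("x")
        assert np.log(hi) - np.log(or_v) == pytest.approx(
            np.log(or_v) - np.log(lo), abs=1e-9
        )


class TestStratify:
    def test_boundary_convention(self):
        s = models.stratify_scores(np.array([20, 21, 80, 81]))
        assert list(s.astype(str)) == ["low", "intermediate", "intermediate", "high"]

    def test_hand_labeling(self):
        s = models.stratify_scores(np.array([1, 25, 50, 75, 99]))
        assert list(s.astype(str)) == [
            "low", "intermediate", "intermediate", "intermediate", "high",
        ]

    def test_uniform_percentiles_proportions(self):
        s = models.stratify_scores(np.repeat(np.arange(1, 101), 10))
        frac = s.value_counts(normalize=True)
        assert frac["low"] == pytest.approx(0.2)
        assert frac["intermediate"] == pytest.approx(0.6)
        assert frac["high"] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            models.stratify_scores(np.array([0, 50]))


class TestSixLevel:
    @staticmethod
    def _simulated(rng, n=20_000, beta_carrier=np.log(3), beta_z=np.log(1.7),
                   carrier_freq=0.05):
        z = rng.standard_normal(n)
        carrier = rng.random(n) < carrier_freq
        eta = -2.0 + beta_carrier * carrier + beta_z * z
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        pct = np.ceil(100 * stats.rankdata(z) / n).astype(int)
        return y, carrier, models.stratify_scores(pct), z, pct

    def test_reference_group_is_unity(self, rng):
        y, carrier, strata, _, _ = self._simulated(rng)
        est, _ = models.six_level_or(y, carrier, strata)
        ref = [e for e in est if not e.carrier and e.score_stratum == "intermediate"]
        assert ref[0].or_value == 1.0 and ref[0].ci_low == 1.0 == ref[0].ci_high

    def test_null_simulation_all_or_near_one(self, rng):
        y, carrier, strata, _, _ = self._simulated(
            rng, beta_carrier=0.0, beta_z=0.0
        )
        est, _ = models.six_level_or(y, carrier, strata)
        for e in est:
            if e.estimable and not np.isnan(e.p):
                assert e.ci_low < 1.3 and e.ci_high > 0.75

    def test_risk_ordering_matches_generator(self, rng):
        y, carrier, strata, _, _ = self._simulated(rng)
        est, _ = models.six_level_or(y, carrier, strata)
        d = {(e.carrier, e.score_stratum): e.or_value for e in est}
        assert d[(True, "high")] > d[(True, "low")]
        assert d[(False, "high")] > d[(False, "low")]
        assert d[(True, "intermediate")] > d[(False, "intermediate")]

    def test_no_carriers_flagged_not_estimable(self, rng):
        y, _, strata, _, _ = self._simulated(rng, n=3000)
        carrier = np.zeros(3000, dtype=bool)
        est, _ = models.six_level_or(y, carrier, strata)
        carrier_levels = [e for e in est if e.carrier]
        assert all(not e.estimable for e in carrier_levels)
        assert sum(e.estimable for e in est) == 3


class TestPerSDAndInteraction:
    def test_permuted_scores_null_or(self, rng):
        n = 10_000
        carrier = rng.random(n) < 0.1
        eta = -1.5 + np.log(3) * carrier
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        z = rng.standard_normal(n)  # independent of outcome
        res = models.or_per_sd_by_stratum(y, z, carrier)
        for stratum in ("carrier", "noncarrier"):
            assert res[stratum]["ci_low"] < 1.0 < res[stratum]["ci_high"]

    def test_stratified_equals_interaction_model_covariate_free(self, rng):
        n = 4000
        carrier = rng.random(n) < 0.3
        z = rng.standard_normal(n)
        eta = -1.0 + 0.5 * z + 1.0 * carrier + 0.4 * z * carrier
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        strat = models.or_per_sd_by_stratum(y, z, carrier)
        inter = models.interaction_test(y, z, carrier)
        fit = inter["fit"]
        # z slope in noncarriers = main z effect; in carriers = main + product
        b_non = np.log(strat["noncarrier"]["or_per_sd"])
        b_car = np.log(strat["carrier"]["or_per_sd"])
        assert fit.coefficients["z"] == pytest.approx(b_non, abs=1e-6)
        assert inter["coef"] == pytest.approx(b_car - b_non, abs=1e-6)

    def test_interaction_power_against_strong_effect(self, rng):
        n = 20_000
        carrier = rng.random(n) < 0.3
        z = rng.standard_normal(n)
        eta = -1.0 + np.log(1.7) * z + (np.log(5.0) - np.log(1.7)) * z * carrier
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = models.interaction_test(y, z, carrier)
        assert res["p"] < 1e-6

    def test_small_stratum_warns(self, rng):
        n = 3000
        carrier = np.zeros(n, dtype=bool)
        carrier[:30] = True
        z = rng.standard_normal(n)
        y = (rng.random(n) < 0.05).astype(float)
        y[:2] = 1  # ensure both classes among carriers
        with pytest.warns(UserWarning, match="events"):
            models.or_per_sd_by_stratum(y, z, carrier)


class TestPercentileCurve:
    @staticmethod
    def _fit(beta_carrier, beta_z, rng, n=30_000, interaction=False, beta_zx=0.0):
        z = rng.standard_normal(n)
        carrier = (rng.random(n) < 0.2).astype(float)
        eta = -1.5 + beta_carrier * carrier + beta_z * z + beta_zx * z * carrier
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cols = {"z": z, "carrier": carrier}
        if interaction:
            cols["z_x_carrier"] = z * carrier
        return models.fit_logistic(y, pd.DataFrame(cols))

    def test_hand_computed_delta_at_90th(self):
        # exp(log 3 + 1.2816 * log 1.6) with exact coefficients
        beta = pd.Series(
            {"intercept": -1.0, "z": np.log(1.6), "carrier": np.log(3.0)}
        )
        fit = models.LogisticFit(
            coefficients=beta,
            covariance=pd.DataFrame(
                np.zeros((3, 3)), index=beta.index, columns=beta.index
            ),
            loglik=0.0, n=1, converged=True,
        )
        z_map = pd.Series(
            stats.norm.ppf((np.arange(1, 101) - 0.5) / 100), index=np.arange(1, 101)
        )
        z_map.loc[50] = 0.0
        z_map.loc[90] = 1.2816
        curve = models.percentile_or_curve(fit, z_map)
        carrier_90 = curve.query("carrier and percentile == 90")["or"].iloc[0]
        assert carrier_90 == pytest.approx(
            np.exp(np.log(3) + 1.2816 * np.log(1.6)), abs=1e-9
        )
        assert carrier_90 == pytest.approx(5.489, abs=0.01)

    def test_noncarrier_median_is_reference(self, rng):
        fit = self._fit(np.log(3), np.log(1.6), rng)
        z_map = models.percentile_z_map(
            rng.standard_normal(20_000),
            np.repeat(np.arange(1, 101), 200),
        )
        curve = models.percentile_or_curve(fit, z_map)
        ref = curve.query("not carrier and percentile == 50")["or"].iloc[0]
        assert ref == pytest.approx(1.0, abs=1e-12)

    def test_zero_score_effect_flat_curves(self, rng):
        fit = self._fit(np.log(3), np.log(1.6), rng)
        fit.coefficients["z"] = 0.0
        z_map = pd.Series(
            stats.norm.ppf((np.arange(1, 101) - 0.5) / 100), index=np.arange(1, 101)
        )
        curve = models.percentile_or_curve(fit, z_map)
        non = curve.query("not carrier")["or"]
        car = curve.query("carrier")["or"]
        np.testing.assert_allclose(non, 1.0)
        np.testing.assert_allclose(car, np.exp(fit.coefficients["carrier"]))

    def test_additive_model_constant_carrier_ratio(self, rng):
        fit = self._fit(np.log(3), np.log(1.6), rng)
        z_map = models.percentile_z_map(
            rng.standard_normal(10_000), np.repeat(np.arange(1, 101), 100)
        )
        curve = models.percentile_or_curve(fit, z_map)
        ratio = (
            curve.query("carrier").set_index("percentile")["or"]
            / curve.query("not carrier").set_index("percentile")["or"]
        )
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_monotone_when_score_coefficient_positive(self, rng):
        from polypen.scores import percentile_map

        fit = self._fit(np.log(3), np.log(1.6), rng)
        values = pd.Series(rng.standard_normal(10_000))
        z_map = models.percentile_z_map(values, percentile_map(values).to_numpy())
        curve = models.percentile_or_curve(fit, z_map)
        for flag in (True, False):
            vals = curve[curve.carrier == flag].sort_values("percentile")["or"]
            assert (np.diff(vals) >= -1e-12).all()


class TestLinearityAndCalibration:
    def test_lrt_nonnegative_and_null_calibrated(self, rng):
        # truly linear generator: LRT p should not be extreme
        n = 5000
        z = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.5 * z)))).astype(float)
        res = models.linearity_lrt(y, z)
        assert res["lrt"] >= 0
        assert res["df"] == 2

    def test_lrt_type_i_error(self):
        rejections = 0
        n_reps = 200
        rng = np.random.default_rng(42)
        for _ in range(n_reps):
            n = 600
            z = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.5 * z)))).astype(float)
            rejections += models.linearity_lrt(y, z)["p"] < 0.05
        rate = rejections / n_reps
        assert abs(rate - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / n_reps) + 0.01

    def test_lrt_detects_quadratic(self, rng):
        n = 8000
        z = rng.standard_normal(n)
        eta = -1.0 + 0.3 * z + 0.5 * z**2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        assert models.linearity_lrt(y, z)["p"] < 1e-6

    def test_calibration_bins_conserve_n(self, rng):
        n = 5000
        pct = rng.integers(1, 101, size=n)
        p_hat = rng.random(n)
        y = (rng.random(n) < p_hat).astype(float)
        tbl = models.calibration_table(p_hat, pct, y)
        assert tbl["n"].sum() == n
        assert len(tbl) == 20

    def test_calibrated_generator_observed_matches_expected(self, rng):
        n = 40_000
        z = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(-1.5 + 0.6 * z)))
        y = (rng.random(n) < p).astype(float)
        pct = np.ceil(100 * stats.rankdata(z) / n).astype(int)
        tbl = models.calibration_table(p, pct, y)
        resid = tbl["observed"] - tbl["expected"]
        se = np.sqrt(tbl["expected"] * (1 - tbl["expected"]) / tbl["n"])
        assert (resid.abs() < 4 * se).all()

    def test_constant_probability_model_flat_expected(self, rng):
        n = 2000
        pct = rng.integers(1, 101, size=n)
        y = (rng.random(n) < 0.3).astype(float)
        tbl = models.calibration_table(np.full(n, 0.3), pct, y)
        assert tbl["expected"].max() - tbl["expected"].min() < 1e-12
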