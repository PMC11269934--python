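"""Statistical layer: Gaussian window, plateau, quadratic, LMM, 2^-ddCt."""

import numpy as np
import pandas as pd
import pytest

from devwindow import (
    GaussianWindowRegressor,
    LinearPlateauRegressor,
    QuadraticRegressor,
    compute_rq,
    fit_gaussian_window,
    fit_linear_plateau,
    fit_quadratic,
    fit_random_intercept_lm,
    marginal_loglik,
)
from devwindow.fits import gaussian_window_curve
from devwindow.simulate import simulate_ct_table, simulate_development_table

PDS = [4, 7, 10, 11, 12, 13, 14, 15, 16, 19, 22, 25]
VM_MODEL = {"a": -52.84, "b": -1.12, "jp": 19.62}  # membrane-potential trajectory


class TestGaussianWindow:
    def test_noiseless_exact_recovery(self):
        x = np.arange(7, 26, dtype=float)
        y = gaussian_window_curve(x, 0.3, 13.0, 1.0)
        fit = fit_gaussian_window(x, y)
        assert fit.kappa == pytest.approx(0.3, abs=1e-8)
        assert fit.mu == pytest.approx(13.0, abs=1e-8)
        assert fit.sigma == pytest.approx(1.0, abs=1e-8)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_pins_mu(self):
        x = np.array([10, 11, 12, 13, 14, 15, 16], dtype=float)
        y = np.array([0.01, 0.05, 0.2, 0.3, 0.2, 0.05, 0.01])
        assert fit_gaussian_window(x, y).mu == pytest.approx(13.0, abs=1e-6)

    def test_peak_prediction_equals_kappa(self):
        reg = GaussianWindowRegressor().fit(
            np.arange(7, 26), gaussian_window_curve(np.arange(7, 26), 0.26, 12.99, 0.65))
        assert reg.predict([reg.mu_])[0] == pytest.approx(reg.kappa_)

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_window([10, 11, 12], [0.1, 0.3, 0.1])


class TestLinearPlateau:
    def test_noiseless_recovery_to_grid_resolution(self):
        table, _ = simulate_development_table(VM_MODEL, 0.0, 0.0, 3, PDS, seed=0)
        fit = fit_linear_plateau(table, random_intercept=False)
        assert abs(fit.jp - VM_MODEL["jp"]) <= 0.05 + 1e-9
        assert fit.a == pytest.approx(VM_MODEL["a"], abs=0.1)
        assert fit.b == pytest.approx(VM_MODEL["b"], abs=0.01)

    def test_prediction_beyond_junction_is_plateau(self):
        table, _ = simulate_development_table(VM_MODEL, 0.0, 0.0, 3, PDS, seed=0)
        reg = LinearPlateauRegressor(random_intercept=False).fit(table["pd"], table["value"])
        pred25 = reg.predict([25.0])[0]
        assert pred25 == pytest.approx(reg.a_ + reg.b_ * reg.jp_)
        assert pred25 == pytest.approx(-74.81, abs=0.1)  # a + b*jp of the generating model

    def test_profile_minimum_at_jp(self):
        table, _ = simulate_development_table(VM_MODEL, 1.0, 3.0, 4, PDS, seed=3)
        reg = LinearPlateauRegressor().fit(
            table["pd"], table["value"], groups=table["animal_id"])
        assert reg.deviance_ <= reg.profile_["deviance"].min() + 1e-9

    def test_flat_data_flagged_linear(self):
        table, _ = simulate_development_table({"a": 5.0, "b": 0.0}, 0.0, 0.0, 3, PDS, seed=0)
        fit = fit_linear_plateau(table, random_intercept=False)
        assert fit.linear_fallback and np.isnan(fit.jp)

    def test_random_intercept_absorbs_animal_effects(self):
        table, _ = simulate_development_table(VM_MODEL, 2.66, 5.0, 5, PDS, seed=11)
        fit = fit_linear_plateau(table, random_intercept=True)
        assert abs(fit.jp - VM_MODEL["jp"]) < 2.5
        assert 0.5 < fit.sd_animal < 8.0


class TestQuadratic:
    GAIN = {"a": 0.24, "b": -0.021, "c": 0.00081}  # firing-gain trajectory

    def test_vertex_value_printed_coefficients(self):
        table, _ = simulate_development_table(self.GAIN, 0.0, 0.0, 3, PDS, seed=0)
        fit = fit_quadratic(table, random_intercept=False)
        assert round(fit.vertex_value, 1) == 0.1
        assert fit.vertex == pytest.approx(-self.GAIN["b"] / (2 * self.GAIN["c"]), abs=0.05)
        assert fit.vertex_is_minimum

    def test_vertex_identity_algebraic(self):
        table, _ = simulate_development_table(self.GAIN, 0.01, 0.02, 4, PDS, seed=5)
        fit = fit_quadratic(table)
        assert fit.vertex_value == pytest.approx(fit.a - fit.b**2 / (4 * fit.c), abs=1e-12)

    def test_symmetric_points_pin_vertex(self):
        x = np.array([8, 10, 12, 14, 16], dtype=float)
        y = (x - 12.0) ** 2
        reg = QuadraticRegressor(random_intercept=False).fit(x, y)
        assert reg.vertex_ == pytest.approx(12.0, abs=1e-8)

    def test_three_points_interpolated_exactly(self):
        x = np.array([1.0, 2.0, 4.0])
        a, b, c = 2.0, -1.5, 0.25
        reg = QuadraticRegressor(random_intercept=False).fit(x, a + b * x + c * x**2)
        assert (reg.a_, reg.b_, reg.c_) == pytest.approx((a, b, c), abs=1e-9)


class TestRandomInterceptLM:
    def make_data(self, sd_animal, sd_resid, seed, n_groups=10, n_per=20):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(n_groups), n_per)
        x = rng.uniform(0, 10, g.size)
        y = (1.0 + 0.8 * x + rng.normal(0, sd_animal, n_groups)[g]
             + rng.normal(0, sd_resid, g.size))
        return np.column_stack([np.ones_like(x), x]), y, g

    def test_zero_variance_reduces_to_ols(self):
        X, y, g = self.make_data(0.0, 1.0, 0)
        res = fit_random_intercept_lm(X, y, groups=g)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.params == pytest.approx(ols, abs=1e-4)

    def test_variance_components_recovered(self):
        sd_a_hat, sd_r_hat = [], []
        for s in range(50):
            X, y, g = self.make_data(2.0, 1.0, s)
            res = fit_random_intercept_lm(X, y, groups=g)
            sd_a_hat.append(res.sd_animal)
            sd_r_hat.append(res.sd_resid)
        assert abs(np.median(sd_a_hat) - 2.0) / 2.0 < 0.25
        assert abs(np.median(sd_r_hat) - 1.0) / 1.0 < 0.25

    def test_loglik_matches_direct_covariance(self):
        X, y, g = self.make_data(1.5, 0.7, 3, n_groups=5, n_per=8)  # 40 rows
        res = fit_random_intercept_lm(X, y, groups=g)
        direct = marginal_loglik(X, y, g, res.params, res.sd_animal, res.sd_resid)
        assert abs(res.loglik - direct) < 1e-6

    def test_matches_statsmodels_ml(self):
        import statsmodels.api as sm

        X, y, g = self.make_data(2.0, 1.0, 7, n_groups=8, n_per=10)
        res = fit_random_intercept_lm(X, y, groups=g)
        m = sm.MixedLM(y, X, groups=g).fit(reml=False)
        assert res.params == pytest.approx(np.asarray(m.fe_params), abs=1e-4)
        assert res.loglik == pytest.approx(m.llf, abs=1e-4)
        assert res.sd_animal == pytest.approx(float(np.sqrt(np.asarray(m.cov_re)[0, 0])), abs=1e-2)

    def test_duplicate_column_names_collinear(self):
        X = np.column_stack([np.ones(20), np.arange(20), np.arange(20)])
        g = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="dup"):
            fit_random_intercept_lm(X, np.arange(20.0), groups=g, names=["a", "b", "dup"])

    def test_reml_flag_runs(self):
        X, y, g = self.make_data(2.0, 1.0, 9)
        res = fit_random_intercept_lm(X, y, groups=g, reml=True)
        assert res.method == "REML" and np.isfinite(res.loglik)


class TestLivak:
    def test_power_identities(self):
        ct_ref = np.array([18.0, 18.0, 18.0, 18.0])
        # reference group ddCt 0 -> RQ 1; +1 cycle -> 0.5; -2 cycles -> 4
        ct_t = np.array([24.0, 24.0, 25.0, 22.0])
        groups = np.array(["ref", "ref", "g1", "g2"])
        res = compute_rq(ct_t, ct_ref, groups, "ref")
        rq = res.samples.set_index("group")["rq"]
        assert rq.loc["ref"].tolist() == [1.0, 1.0]
        assert rq.loc["g1"] == 0.5
        assert rq.loc["g2"] == 4.0

    def test_reference_group_geometric_mean_is_one(self):
        table = simulate_ct_table(seed=21)
        res = compute_rq(table["ct_target"], table["ct_ref"], table["group"], 4)
        summary = res.group_summary.set_index("group")
        assert summary.loc[4, "rq_geomean"] == pytest.approx(1.0, abs=1e-12)

    def test_missing_ct_excluded(self):
        ct_t = np.array([24.0, np.nan, 25.0])
        ct_r = np.array([18.0, 18.0, 18.0])
        res = compute_rq(ct_t, ct_r, np.array(["ref", "ref", "g1"]), "ref")
        assert res.n_excluded == 1 and len(res.samples) == 2

    def test_expression_declines_with_age(self):
        table = simulate_ct_table(seed=2)
        res = compute_rq(table["ct_target"], table["ct_ref"], table["group"], 4)
        s = res.group_summary.set_index("group")["rq_geomean"]
        assert s.loc[4] > s.loc[13] > s.loc[25]
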