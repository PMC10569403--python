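import numpy as np
import pytest
from scipy import stats

from intelligrowth.betareg import (
    fit_beta_growth,
    intercept_only_loglik,
    load_model,
    model_cdf,
    model_density,
    model_quantile,
    predict_distribution,
    quantile_curve,
    save_model,
    _squeeze_boundary,
)
from intelligrowth.synthetic import TD_TRUTH, generate_td_cohort, true_quantile

from conftest import constant_model


class TestConstantModelLinks:
    def test_zero_coefs_give_half_mean_unit_precision(self):
        m = constant_model(0.5, 1.0)
        d = predict_distribution(m, 60)
        assert d.mu == pytest.approx(0.5)
        assert d.phi == pytest.approx(1.0)

    def test_uniform_quantile_closed_form(self):
        m = constant_model(0.5, 2.0)  # Beta(1, 1) = uniform
        assert model_quantile(m, 48, 0.10) == pytest.approx(0.10, abs=1e-12)

    def test_beta21_cdf_closed_form(self):
        m = constant_model(2 / 3, 3.0)  # Beta(2, 1), cdf y^2
        assert model_cdf(m, 48, 0.5) == pytest.approx(0.25, abs=1e-12)
        assert model_density(m, 48, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_quantile_cdf_roundtrip(self):
        m = constant_model(0.7, 11.0)
        for p in (0.37, 0.05, 0.99):
            assert model_cdf(m, 60, model_quantile(m, 60, p)) == pytest.approx(
                p, abs=1e-8
            )

    def test_out_of_range_arguments_rejected(self):
        m = constant_model(0.5, 2.0)
        with pytest.raises(ValueError):
            model_quantile(m, 60, 1.5)
        with pytest.raises(ValueError):
            model_density(m, 60, 1.0)
        with pytest.raises(ValueError, match="extrapolation"):
            predict_distribution(m, 120)


class TestFitting:
    def test_recovers_constant_distribution(self):
        rng = np.random.default_rng(42)
        ages = rng.uniform(30, 96, 2000)
        y = rng.beta(0.7 * 10, 0.3 * 10, 2000)
        model = fit_beta_growth(ages=ages, scores=y)
        grid = np.linspace(*model.age_range, 20)
        mus = np.array([predict_distribution(model, a).mu for a in grid])
        np.testing.assert_allclose(mus, 0.7, atol=0.02)

    def test_refit_is_deterministic(self, td_cohort):
        m1 = fit_beta_growth(td_cohort)
        m2 = fit_beta_growth(td_cohort)
        np.testing.assert_array_equal(m1.mean_coefs, m2.mean_coefs)
        np.testing.assert_array_equal(m1.precision_coefs, m2.precision_coefs)

    def test_median_curve_recovery_against_oracle(self, td_model_large):
        ages = np.arange(36, 91)
        fit_q = quantile_curve(td_model_large, 0.5, ages)
        true_q = np.array([true_quantile(TD_TRUTH, a, 0.5) for a in ages])
        assert np.max(np.abs(fit_q - true_q)) < 0.03

    def test_requires_twenty_observations(self):
        with pytest.raises(ValueError, match="20 observations"):
            fit_beta_growth(ages=np.arange(30, 40), scores=np.full(10, 0.5))

    def test_boundary_scores_squeezed(self):
        y = np.array([0.0, 1.0, 0.5, 0.5])
        out = _squeeze_boundary(y)
        assert np.all((out > 0) & (out < 1))
        assert out[2] == 0.5  # interior untouched
        assert out[0] == pytest.approx(0.5 / 4)

    def test_nesting_beats_intercept_only(self, td_cohort, td_model):
        assert td_model.loglik >= intercept_only_loglik(td_cohort.scores) - 1e-6

    def test_matches_independent_beta_regression(self, td_cohort, td_model):
        """Cross-check: statsmodels' beta MLE polished from our optimum
        neither moves the parameters nor improves the likelihood."""
        from statsmodels.genmod.families.links import Log
        from statsmodels.othermod.betareg import BetaModel

        y = _squeeze_boundary(td_cohort.scores)
        Xm = td_model.mean_basis.design(td_cohort.ages)
        Xp = td_model.precision_basis.design(td_cohort.ages)
        bm = BetaModel(y, Xm, exog_precision=Xp, link_precision=Log())
        start = np.concatenate([td_model.mean_coefs, td_model.precision_coefs])
        res = bm.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
        assert res.llf == pytest.approx(td_model.loglik, abs=1e-4)
        np.testing.assert_allclose(res.params, start, atol=1e-3)
        # and from its own start it finds nothing better
        own = bm.fit(method="bfgs", maxiter=2000, disp=0)
        assert td_model.loglik >= own.llf - 1e-3


class TestQuantileCurves:
    def test_curves_never_cross(self, td_model):
        ages = np.arange(30, 97)
        levels = [0.05, 0.10, 0.50, 0.90, 0.95]
        curves = [quantile_curve(td_model, p, ages) for p in levels]
        for lower, upper in zip(curves, curves[1:]):
            assert np.all(lower < upper)

    def test_grid_matches_pointwise_quantile(self, td_model):
        ages = np.array([36.0, 60.0, 84.0])
        grid = quantile_curve(td_model, 0.1, ages)
        point = [model_quantile(td_model, a, 0.1) for a in ages]
        np.testing.assert_allclose(grid, point, atol=1e-12)

    def test_grid_outside_boundaries_rejected(self, td_model):
        with pytest.raises(ValueError):
            quantile_curve(td_model, 0.5, np.array([20.0, 60.0]))


class TestRecoveryAcrossReplicates:
    def test_tenth_percentile_mae_small_at_n500(self):
        """Across 50 replicates at n=500, the mean absolute error of the
        fitted 10th-percentile curve against the generator truth stays
        below 0.05 over ages 36-90."""
        ages = np.arange(36, 91)
        true_q = np.array([true_quantile(TD_TRUTH, a, 0.1) for a in ages])
        maes = []
        for rep in range(50):
            coh = generate_td_cohort(500, seed=300 + rep)
            model = fit_beta_growth(coh)
            maes.append(np.mean(np.abs(quantile_curve(model, 0.1, ages) - true_q)))
        assert np.mean(maes) < 0.05


class TestParameterizationEquivalence:
    def test_mean_sigma_density_matches(self):
        """phi = (1 - sigma^2)/sigma^2 maps the mean-sigma beta onto the
        mean-precision beta: densities agree to 1e-10 on a grid."""
        mu, phi = 0.62, 9.0
        sigma2 = 1.0 / (1.0 + phi)
        a = mu * (1.0 - sigma2) / sigma2
        b = (1.0 - mu) * (1.0 - sigma2) / sigma2
        m = constant_model(mu, phi)
        grid = np.linspace(0.01, 0.99, 99)
        np.testing.assert_allclose(
            [model_density(m, 60, y) for y in grid],
            stats.beta.pdf(grid, a, b),
            atol=1e-10,
        )


class TestSerialization:
    def test_save_load_roundtrip(self, td_model, tmp_path):
        path = tmp_path / "model.txt"
        save_model(td_model, path)
        back = load_model(path)
        ages = np.linspace(30, 96, 15)
        for a in ages:
            d1, d2 = predict_distribution(td_model, a), predict_distribution(back, a)
            assert d1.mu == pytest.approx(d2.mu, abs=0)
            assert d1.phi == pytest.approx(d2.phi, abs=0)
        assert back.loglik == td_model.loglik
        assert back.n_obs == td_model.n_obs
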