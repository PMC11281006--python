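import numpy as np
import pytest

from specfluor.errors import ConfigError, FitError
from specfluor.evaluation import (
    bootstrap_train,
    evaluate_empirical_panel,
    fit_species_mlr,
    metrics,
    relative_importance_lmg,
)


def _species(n, levels=("a", "b", "c")):
    return np.array([levels[i % len(levels)] for i in range(n)], dtype=object)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r_squared, m.pearson_r, m.rmse, m.mae) == (1.0, 1.0, 0.0, 0.0)

    def test_hand_computed_values(self):
        m = metrics([0.0, 1.0, 3.0], [0.0, 1.0, 2.0])
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.mae == pytest.approx(1 / 3)

    def test_constant_prediction_zero_r2_na_r(self):
        obs = np.array([0.0, 1.0, 2.0])
        m = metrics(np.full(3, obs.mean()), obs)
        assert m.r_squared == pytest.approx(0.0)
        assert np.isnan(m.pearson_r)

    def test_constant_observations_na(self):
        m = metrics([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        assert np.isnan(m.r_squared)

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pred, obs = rng.standard_normal(30), rng.standard_normal(30)
            m = metrics(pred, obs)
            assert m.mae <= m.rmse + 1e-12

    def test_r2_equals_r_squared_for_own_ols_fit(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        y = 1.5 * x + rng.standard_normal(200)
        slope, intercept = np.polyfit(x, y, 1)
        m = metrics(intercept + slope * x, y)
        assert m.r_squared == pytest.approx(m.pearson_r**2, abs=1e-10)


class TestSpeciesMlr:
    def test_null_species_effect_recovers_slope(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(60)
        y = 2 * x + 1
        fit = fit_species_mlr(x, _species(60), y)
        coef = dict(zip(fit.model.exog_names, fit.params))
        assert coef["index"] == pytest.approx(2.0, abs=1e-10)
        assert coef["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert abs(coef["species[b]"]) < 1e-10

    def test_exact_offset_recovery(self):
        rng = np.random.default_rng(3)
        n = 90
        x = rng.standard_normal(n)
        sp = _species(n)
        offsets = {"a": 0.0, "b": 0.4, "c": -0.2}
        y = x + np.array([offsets[s] for s in sp])
        fit = fit_species_mlr(x, sp, y)
        coef = dict(zip(fit.model.exog_names, fit.params))
        assert coef["species[b]"] == pytest.approx(0.4, abs=1e-10)
        assert coef["species[c]"] == pytest.approx(-0.2, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    def test_single_species_rejected(self):
        with pytest.raises(ConfigError):
            fit_species_mlr(np.arange(5.0), np.array(["a"] * 5), np.arange(5.0))

    def test_collinear_design_rejected(self):
        sp = np.array(["a", "a", "b", "b"], dtype=object)
        x = np.array([0.0, 0.0, 1.0, 1.0])  # index == dummy
        with pytest.raises(FitError):
            fit_species_mlr(x, sp, np.array([0.0, 0.1, 1.0, 1.1]))


class TestBootstrap:
    def _data(self, n=80, noise=0.3, seed=4):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        sp = _species(n)
        y = 1.2 * x + 0.5 + noise * rng.standard_normal(n)
        return x, sp, y

    def test_deterministic_under_seed(self):
        x, sp, y = self._data()
        a = bootstrap_train(x, sp, y, n_boot=50, seed=9)
        b = bootstrap_train(x, sp, y, n_boot=50, seed=9)
        np.testing.assert_array_equal(a.coef_boot_mean, b.coef_boot_mean)
        assert a.metrics == b.metrics

    def test_noiseless_data_collapses_intervals(self):
        x, sp, _ = self._data()
        y = 3 * x - 0.7
        rep = bootstrap_train(x, sp, y, n_boot=50, seed=0)
        np.testing.assert_allclose(rep.coef_ci_low, rep.coef_ci_high, atol=1e-9)
        np.testing.assert_allclose(rep.coef_boot_mean, rep.coef_full, atol=1e-9)
        assert rep.metrics.r_squared == pytest.approx(1.0)

    def test_boot_mean_approaches_full_ols(self):
        x, sp, y = self._data(n=150)
        rep = bootstrap_train(x, sp, y, n_boot=2000, seed=1)
        # bootstrap SE of the slope bounds the deviation
        slope_se = np.std(
            [rep.coef_ci_high[1] - rep.coef_ci_low[1]]
        )  # interval width ~ 4 SE
        tol = (rep.coef_ci_high[1] - rep.coef_ci_low[1]) / 4 / np.sqrt(2000) * 5
        assert abs(rep.coef_boot_mean[1] - rep.coef_full[1]) < max(tol, 5e-3)

    def test_oob_metrics_present_and_weaker(self):
        x, sp, y = self._data(noise=0.5)
        rep = bootstrap_train(x, sp, y, n_boot=200, seed=2)
        assert rep.oob_metrics is not None
        assert rep.oob_metrics.r_squared <= rep.metrics.r_squared + 0.05

    def test_invalid_n_boot(self):
        x, sp, y = self._data()
        with pytest.raises(ConfigError):
            bootstrap_train(x, sp, y, n_boot=0)


class TestLmg:
    def test_shares_sum_to_model_r2(self):
        x, sp, y = TestBootstrap()._data(n=120, noise=0.4)
        shares = relative_importance_lmg(x, sp, y)
        assert shares["index"] + shares["species"] == pytest.approx(
            shares["model_r2"], abs=1e-9
        )
        assert shares["index"] >= -1e-9 and shares["species"] >= -1e-9

    def test_species_explains_nothing(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        y = x + 0.2 * rng.standard_normal(300)
        shares = relative_importance_lmg(x, _species(300), y)
        assert shares["species"] == pytest.approx(0.0, abs=0.02)
        assert shares["index"] == pytest.approx(shares["model_r2"], abs=0.02)

    def test_orthogonal_design_shares_match_marginals(self):
        """Balanced species, independent index: LMG share ~ marginal R^2."""
        rng = np.random.default_rng(6)
        n = 2000
        sp = _species(n, ("a", "b", "c", "d", "e", "f"))
        effects = dict(zip("abcdef", np.linspace(-0.3, 0.3, 6)))
        x = rng.standard_normal(n)
        y = 0.5 * x + np.array([effects[s] for s in sp]) + 0.4 * rng.standard_normal(n)
        shares = relative_importance_lmg(x, sp, y)
        ones = np.ones(n)
        marg_index = np.corrcoef(x, y)[0, 1] ** 2
        # marginal species R^2 via group means
        import pandas as pd

        fitted = pd.Series(y).groupby(pd.Series(sp)).transform("mean").to_numpy()
        marg_species = 1 - np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2)
        assert shares["index"] == pytest.approx(marg_index, abs=0.02)
        assert shares["species"] == pytest.approx(marg_species, abs=0.02)


class TestEmpiricalPanel:
    def test_null_data_has_low_r2(self, small_dataset):
        from specfluor import derive_table

        _, spectra, fluor = small_dataset
        params = derive_table(fluor)
        panel = evaluate_empirical_panel(spectra, params)
        assert panel["r2"].median() < 0.1
        assert set(panel["stars"].unique()) <= {"**", "*", "ns", "skipped"}
        # every group x parameter x index combination present
        assert len(panel) == 2 * 6 * 10

    def test_deterministic(self, small_dataset):
        from specfluor import derive_table

        _, spectra, fluor = small_dataset
        params = derive_table(fluor)
        a = evaluate_empirical_panel(spectra, params)
        b = evaluate_empirical_panel(spectra, params)
        assert a.equals(b)
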