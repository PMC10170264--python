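import numpy as np
import pandas as pd
import pytest

from pseudorisk import SimConfig, generate_cohort
from pseudorisk.design import build_design
from pseudorisk.models import (CoxRiskModel, PooledRegressionModel,
                               PseudoCloglogRisk, PseudoMLPRisk,
                               PseudoXGBRisk, fit_pooled_cloglog,
                               fit_pooled_cox, pool_coefficients,
                               select_predictors)
from pseudorisk.pseudo import jackknife_pseudovalues


@pytest.fixture(scope="module")
def fitted_cox(small_cohort):
    X, meta = build_design(small_cohort, ["age", "stage", "er"])
    y = pd.DataFrame({"time": small_cohort["time"],
                      "event": small_cohort["cause"] == 1})
    cont = meta.loc[meta["type"] == "continuous", "term"].tolist()
    return CoxRiskModel(continuous_cols=cont).fit(X, y), X


class TestCox:
    def test_risk_formula_arithmetic(self, fitted_cox):
        model, X = fitted_cox
        # S0=0.9, Xb=log 2 -> 1 - 0.9^2 = 0.19
        model2 = CoxRiskModel()
        model2.coef_ = pd.Series({"z": 1.0})
        model2.centers_ = pd.Series({"z": 0.0})
        model2.baseline_survival_ = 0.9
        assert model2.predict(pd.DataFrame({"z": [np.log(2.0)]}))[0] == \
            pytest.approx(1.0 - 0.81)
        # Xb = 0 -> 1 - S0; S0 = 1 -> 0 regardless of Xb
        assert model2.predict(pd.DataFrame({"z": [0.0]}))[0] == \
            pytest.approx(0.1)
        model2.baseline_survival_ = 1.0
        assert model2.predict(pd.DataFrame({"z": [5.0]}))[0] == 0.0

    def test_predictions_in_unit_interval(self, fitted_cox):
        model, X = fitted_cox
        p = model.predict(X)
        assert np.all((p >= 0) & (p <= 1))

    def test_zero_events_error(self):
        X = pd.DataFrame({"z": [0.1, 0.2, 0.3]})
        y = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [False] * 3})
        with pytest.raises(ValueError):
            CoxRiskModel().fit(X, y)

    def test_recovers_sign_of_strong_binary_effect(self):
        rng = np.random.default_rng(12)
        n = 2000
        z = rng.binomial(1, 0.5, n)
        t = rng.exponential(np.exp(-1.2 * z), n)
        X = pd.DataFrame({"z": z.astype(float)})
        y = pd.DataFrame({"time": t, "event": np.ones(n, bool)})
        m = CoxRiskModel().fit(X, y)
        assert m.coef_["z"] > 0
        assert abs(m.coef_["z"] - 1.2) < 4 * m.se_["z"]

    def test_null_covariate_type_one_error_rate(self):
        # a noise covariate should reach P<0.05 in about 5% of replicates
        from scipy import stats
        rng = np.random.default_rng(100)
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 120
            t = rng.exponential(1.0, n)
            X = pd.DataFrame({"z": rng.normal(size=n)})
            y = pd.DataFrame({"time": t, "event": np.ones(n, bool)})
            m = CoxRiskModel().fit(X, y)
            p = 2 * stats.norm.sf(abs(m.coef_["z"] / m.se_["z"]))
            rejections += p < 0.05
        assert 0.005 < rejections / reps < 0.105


class TestCloglog:
    def test_closed_form_at_zero_linear_predictor(self):
        m = PseudoCloglogRisk()
        m.coef_ = pd.Series({"const": 0.0, "z": 0.0})
        m.columns_ = ["const", "z"]
        p = m.predict(pd.DataFrame({"z": [3.7]}))
        assert p[0] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)

    def test_link_round_trip(self):
        m = PseudoCloglogRisk()
        m.coef_ = pd.Series({"const": -0.3, "z": 0.7})
        m.columns_ = ["const", "z"]
        z = np.linspace(-3, 3, 11)
        lp = m.linear_predictor(pd.DataFrame({"z": z}))
        p = m.predict(pd.DataFrame({"z": z}))
        np.testing.assert_allclose(np.log(-np.log1p(-p)), lp, atol=1e-12)
        assert np.all((p > 0) & (p < 1))
        assert np.all(np.diff(p) > 0)   # monotone in the linear predictor

    def test_intercept_only_matches_marginal_estimate(self, small_cohort):
        pv = jackknife_pseudovalues(small_cohort["time"],
                                    small_cohort["cause"], 10.0).values
        m = PseudoCloglogRisk().fit(pd.DataFrame(index=range(len(pv))), pv)
        fitted = m.predict(pd.DataFrame(index=[0]))[0]
        assert fitted == pytest.approx(pv.mean(), abs=1e-6)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            PseudoCloglogRisk(add_intercept=False).fit(
                pd.DataFrame(index=range(5)), np.zeros(5))
        with pytest.raises(ValueError):
            PseudoCloglogRisk().fit(pd.DataFrame({"z": np.arange(5.0)}),
                                    np.full(5, 0.4))


class TestSelectionRule:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "df",
                                           "p", "variable", "type"])

    def test_magnitude_and_significance_rule(self):
        from scipy import stats
        tbl = self._table([
            # HR 1.05 at P=0.001: significant but too small -> excluded
            ("a", np.log(1.05), 0.01, np.inf, 0.001, "a", "binary"),
            # HR 1.25 at P=0.004 -> included
            ("b", np.log(1.25), 0.07, np.inf, 0.004, "b", "binary"),
            # continuous FP term at P=0.02 -> excluded (needs P<0.01)
            ("c_fp1", 0.4, 0.17, np.inf, 0.02, "c", "continuous"),
            # continuous at P=0.001 -> included
            ("d", 0.2, 0.05, np.inf, 0.001, "d", "continuous"),
        ])
        assert select_predictors(tbl) == ["b", "d"]

    def test_multilevel_kept_whole_if_any_level_qualifies(self):
        tbl = self._table([
            ("s_2", np.log(1.02), 0.1, np.inf, 0.5, "s", "categorical"),
            ("s_3", np.log(1.60), 0.1, np.inf, 0.001, "s", "categorical"),
        ])
        assert select_predictors(tbl) == ["s"]

    def test_permutation_invariance(self):
        rows = [
            ("a", np.log(1.3), 0.05, np.inf, 0.001, "a", "binary"),
            ("b", np.log(0.85), 0.04, np.inf, 0.002, "b", "binary"),
            ("c", 0.01, 0.5, np.inf, 0.9, "c", "continuous"),
        ]
        tbl = self._table(rows)
        shuffled = self._table([rows[2], rows[0], rows[1]])
        assert set(select_predictors(tbl)) == set(select_predictors(shuffled))


class TestMLModels:
    def test_clipping(self):
        m = PseudoXGBRisk()
        m.predict_raw = lambda X: np.array([-0.2, 1.4, 0.3])
        np.testing.assert_allclose(m.predict(None), [0.0, 1.0, 0.3])

    def test_constant_target_regression(self):
        X = pd.DataFrame({"z": np.linspace(0, 1, 64)})
        y = np.full(64, 0.37)
        gbt = PseudoXGBRisk(n_rounds=1, max_depth=1, eta=1.0, subsample=1.0,
                            colsample_bytree=1.0, colsample_bylevel=1.0,
                            seed=0).fit(X, y)
        np.testing.assert_allclose(gbt.predict(X), 0.37, atol=1e-6)
        mlp = PseudoMLPRisk(n_hidden_layers=1, n_units=8, epochs=50,
                            batch_size=8, learning_rate=0.05, seed=0).fit(X, y)
        assert np.max(np.abs(mlp.predict(X) - 0.37)) < 0.05

    def test_gbt_seed_reproducibility(self, small_cohort):
        X, _ = build_design(small_cohort)
        pv = jackknife_pseudovalues(small_cohort["time"],
                                    small_cohort["cause"], 10.0).values
        a = PseudoXGBRisk(n_rounds=15, seed=3).fit(X, pv).predict(X)
        b = PseudoXGBRisk(n_rounds=15, seed=3).fit(X, pv).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_learners_recover_single_covariate_signal(self):
        cfg = SimConfig(n_subjects=5000, censor_rate=0.0, region_sigma=0.0,
                        beta_sub={"age_std": 1.2},
                        beta_competing={"age_std": 0.2}, seed=44)
        df = generate_cohort(cfg)
        pv = jackknife_pseudovalues(df["time"], df["cause"], 10.0).values
        X = pd.DataFrame({"age": df["age"].to_numpy()})
        from scipy.stats import spearmanr
        for model in (PseudoXGBRisk(n_rounds=150, eta=0.1, seed=0),
                      PseudoMLPRisk(epochs=30, seed=0)):
            pred = model.fit(X, pv).predict(X)
            rho = spearmanr(pred, df["truth"]).statistic
            assert rho > 0.8


class TestPooledModels:
    def test_pooled_cox_equals_single_fit_for_identical_datasets(self, small_cohort):
        datasets = [small_cohort, small_cohort]
        model, fits = fit_pooled_cox(datasets, ["age", "er", "stage"])
        assert model.coef_table["se"].gt(0).all()
        np.testing.assert_allclose(fits[0].coef_, fits[1].coef_)
        pred = model.predict(small_cohort)
        assert np.all((pred >= 0) & (pred <= 1))

    def test_serialisation_round_trip_bit_identical(self, small_cohort):
        pv = jackknife_pseudovalues(small_cohort["time"],
                                    small_cohort["cause"], 10.0).values
        model, _ = fit_pooled_cloglog([small_cohort, small_cohort], pv,
                                      ["age", "stage", "er"])
        clone = PooledRegressionModel.from_json(model.to_json())
        np.testing.assert_array_equal(model.predict(small_cohort),
                                      clone.predict(small_cohort))
        cox, _ = fit_pooled_cox([small_cohort, small_cohort], ["age", "er"])
        clone2 = PooledRegressionModel.from_json(cox.to_json())
        np.testing.assert_array_equal(cox.predict(small_cohort),
                                      clone2.predict(small_cohort))
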