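import numpy as np
import pandas as pd
import pytest

from pseudorisk.meta import (hksj_random_effects, meta_regression,
                             pool_metric_over_imputations)
from pseudorisk.metrics import ClusterMetric
from pseudorisk.impute import rubin_pool

# Reference values computed before the build with R metafor 4.8-0
# (rma(yi, sei, method="DL", test="knha"); predict(..., pi.type="Riley")).
METAFOR_3STUDY = {
    "estimates": [0.80, 0.85, 0.90], "ses": [0.02, 0.02, 0.02],
    "pooled": 0.85, "se": 0.028867513459, "ci": (0.725793114412,
                                                 0.974206885588),
    "tau2": 0.0021, "i2": 84.0, "pi": (0.1618, 1.5382),
}
METAFOR_5STUDY = {
    "estimates": [0.7, 0.9, 0.82, 0.65, 1.02],
    "ses": [0.05, 0.08, 0.03, 0.06, 0.1],
    "pooled": 0.799557285600, "se": 0.062182818531,
    "ci": (0.626910103463, 0.972204467738),
    "tau2": 0.009829802980, "i2": 76.281051949888, "pi": (0.4271, 1.1720),
}


class TestHKSJ:
    @pytest.mark.parametrize("ref", [METAFOR_3STUDY, METAFOR_5STUDY],
                             ids=["k3", "k5"])
    def test_matches_independent_reference(self, ref):
        m = hksj_random_effects(ref["estimates"], ref["ses"])
        assert m.estimate == pytest.approx(ref["pooled"], abs=1e-8)
        assert m.se == pytest.approx(ref["se"], abs=1e-8)
        assert m.ci_low == pytest.approx(ref["ci"][0], abs=1e-8)
        assert m.ci_high == pytest.approx(ref["ci"][1], abs=1e-8)
        assert m.tau2 == pytest.approx(ref["tau2"], abs=1e-8)
        assert m.i2 == pytest.approx(ref["i2"], abs=1e-6)
        assert m.pi_low == pytest.approx(ref["pi"][0], abs=1e-4)
        assert m.pi_high == pytest.approx(ref["pi"][1], abs=1e-4)

    def test_homogeneous_input(self):
        m = hksj_random_effects([0.8, 0.8, 0.8, 0.8], [0.05] * 4)
        assert m.estimate == pytest.approx(0.8)
        assert m.tau2 == 0.0 and m.i2 == 0.0

    def test_equal_ses_no_heterogeneity_pools_to_mean(self):
        y = [0.78, 0.80, 0.82]
        m = hksj_random_effects(y, [0.5] * 3)   # huge ses: tau2 truncates to 0
        assert m.estimate == pytest.approx(np.mean(y))

    def test_pi_contains_ci(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            k = int(rng.integers(3, 12))
            y = rng.normal(0.8, 0.1, k)
            se = rng.uniform(0.01, 0.1, k)
            m = hksj_random_effects(y, se)
            assert m.pi_low <= m.ci_low + 1e-12
            assert m.pi_high >= m.ci_high - 1e-12
            assert 0.0 <= m.i2 < 100.0

    def test_k2_has_ci_but_no_pi(self):
        m = hksj_random_effects([0.7, 0.9], [0.05, 0.05])
        assert np.isfinite(m.ci_low) and np.isnan(m.pi_low)

    def test_validation(self):
        with pytest.raises(ValueError):
            hksj_random_effects([0.8], [0.1])
        with pytest.raises(ValueError):
            hksj_random_effects([0.8, 0.9], [0.1, 0.0])


class TestMetaRegression:
    def test_generating_covariate_explains_heterogeneity(self):
        rng = np.random.default_rng(2)
        x = np.linspace(-1, 1, 10)
        y = 0.8 + 0.2 * x + rng.normal(0, 1e-4, 10)
        res = meta_regression(y, np.full(10, 1e-3), pd.DataFrame({"x": x}))
        assert res.r2 > 99.0
        assert res.tau2 < res.tau2_null

    def test_noise_covariate_on_homogeneous_data_clips_to_zero(self):
        res = meta_regression([0.8] * 8, [0.05] * 8,
                              pd.DataFrame({"x": np.arange(8.0)}))
        assert res.r2 == 0.0

    def test_r2_never_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = 9
            y = rng.normal(0.8, 0.05, k)
            res = meta_regression(y, rng.uniform(0.02, 0.05, k),
                                  pd.DataFrame({"x": rng.normal(size=k)}))
            assert 0.0 <= res.r2 <= 100.0

    def test_collinear_covariates_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError):
            meta_regression(np.random.default_rng(0).normal(0.8, 0.1, 8),
                            [0.05] * 8,
                            pd.DataFrame({"a": x, "b": 2 * x}))

    def test_needs_enough_clusters(self):
        with pytest.raises(ValueError):
            meta_regression([0.8, 0.9, 0.7], [0.05] * 3,
                            pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


class TestPoolOverImputations:
    def _metrics(self, values, ses, region="A"):
        return [ClusterMetric("slope", v, s, region=region, imputation=j + 1)
                for j, (v, s) in enumerate(zip(values, ses))]

    def test_identical_metrics_pool_unchanged(self):
        pooled = pool_metric_over_imputations(
            self._metrics([1.1, 1.1, 1.1], [0.2, 0.2, 0.2]))
        assert pooled[0].value == pytest.approx(1.1)
        assert pooled[0].se == pytest.approx(0.2)

    def test_delegates_to_rubin_rules(self):
        values, ses = [1.0, 1.3], [0.2, 0.25]
        pooled = pool_metric_over_imputations(self._metrics(values, ses))
        ref = rubin_pool(values, np.array(ses) ** 2)
        assert pooled[0].value == pytest.approx(ref.estimate)
        assert pooled[0].se == pytest.approx(ref.se)

    def test_pooled_se_at_least_mean_within(self):
        values, ses = [0.9, 1.4, 1.1], [0.2, 0.2, 0.2]
        pooled = pool_metric_over_imputations(self._metrics(values, ses))
        assert pooled[0].se >= 0.2

    def test_inconsistent_labels_rejected(self):
        ms = self._metrics([1.0, 1.1], [0.2, 0.2])
        ms[1].imputation = 1   # duplicate index within one cluster
        with pytest.raises(ValueError):
            pool_metric_over_imputations(ms)


def test_tau2_estimator_is_unbiased_and_pi_covers_new_cluster():
    """Simulation: tau^2 moment estimator unbiased; 95% PI covers a new
    cluster's true effect at about the nominal rate when heterogeneity
    dominates the within-cluster error."""
    rng = np.random.default_rng(2024)
    tau2_hats = []
    hits = 0
    N = 500
    for _ in range(N):
        k, mu, tau = 10, 0.85, 0.08
        se = rng.uniform(0.01, 0.02, k)
        theta = rng.normal(mu, tau, k)
        y = rng.normal(theta, se)
        m = hksj_random_effects(y, se)
        tau2_hats.append(m.tau2)
        new = rng.normal(mu, tau)
        hits += (m.pi_low <= new <= m.pi_high)
    assert np.mean(tau2_hats) == pytest.approx(0.08 ** 2, rel=0.15)
    assert 0.92 < hits / N < 0.98
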