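import numpy as np
import pandas as pd
import pytest

from pseudorisk.metrics import (calibration_slope_citl, citl_only, crude_rate,
                                decision_curve, harrells_c, ipcw_c_index,
                                smoothed_calibration_curve, subgroup_metrics)
from pseudorisk.nonparametric import censoring_survival
from pseudorisk.pseudo import jackknife_pseudovalues


class TestCrudeRate:
    def test_published_cohort_arithmetic(self):
        r = crude_rate(20_367, 688_564.81)
        assert round(r.rate, 2) == 295.79
        r2 = crude_rate(8_808, 297_066.74)
        assert round(r2.rate, 2) == 296.50
        assert round(r2.ci_low, 2) == 290.37
        assert round(r2.ci_high, 2) == 302.76

    def test_log_symmetric_identity(self):
        r = crude_rate(137, 5000.0)
        assert r.ci_low * r.ci_high == pytest.approx(r.rate ** 2, rel=1e-12)

    def test_zero_events(self):
        r = crude_rate(0, 1000.0)
        assert r.rate == 0.0 and np.isnan(r.ci_low) and np.isnan(r.ci_high)

    def test_positive_person_years_required(self):
        with pytest.raises(ValueError):
            crude_rate(10, 0.0)


def _brute_harrell(time, event, risk, horizon):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if not (event[i] and time[i] <= horizon):
            continue
        for j in range(n):
            if time[j] > time[i]:
                den += 1
                num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
    return num / den


class TestHarrellsC:
    def test_perfect_ordering_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        r = np.array([0.9, 0.7, 0.5, 0.3])
        assert harrells_c(t, [1, 1, 1, 1], r, 10.0).value == 1.0

    def test_constant_risk_gives_half(self):
        t = np.linspace(1, 5, 20)
        assert harrells_c(t, np.ones(20, int), np.full(20, 0.4),
                          10.0).value == 0.5

    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(3, 100)
        e = rng.integers(0, 2, 100)
        r = rng.random(100)
        cm = harrells_c(t, e, r, 4.0)
        assert cm.value == pytest.approx(_brute_harrell(t, e, r, 4.0),
                                         abs=1e-10)
        assert cm.se > 0

    def test_no_usable_pairs_errors(self):
        with pytest.raises(ValueError):
            harrells_c([1.0, 2.0], [0, 0], [0.1, 0.2], 10.0)


def _brute_ipcw(time, cause, risk, horizon):
    g = censoring_survival(time, cause)
    gm = np.asarray(g.left_limit(time), float)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if not (cause[i] == 1 and time[i] <= horizon):
            continue
        for j in range(n):
            if j == i:
                continue
            if time[j] > time[i]:
                w = 1.0 / gm[i] ** 2 if gm[i] > 0 else 0.0
            elif cause[j] == 2 and time[j] <= time[i]:
                w = (1.0 / (gm[i] * gm[j])
                     if gm[i] > 0 and gm[j] > 0 else 0.0)
            else:
                continue
            den += w
            num += w * (1.0 if risk[i] > risk[j]
                        else (0.5 if risk[i] == risk[j] else 0.0))
    return num / den


class TestIPCWC:
    def test_equals_weighted_pair_enumeration(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(3, 100)
        c = rng.choice([0, 1, 2], 100, p=[0.3, 0.4, 0.3])
        r = rng.random(100)
        cm = ipcw_c_index(t, c, r, 4.0)
        assert cm.value == pytest.approx(_brute_ipcw(t, c, r, 4.0), abs=1e-10)

    def test_reduces_to_unweighted_without_censoring(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(3, 120)
        c = rng.choice([1, 2], 120)
        r = rng.random(120)
        cm = ipcw_c_index(t, c, r, 5.0)
        # unweighted competing-risks concordance by direct enumeration
        num = den = 0.0
        for i in range(120):
            if not (c[i] == 1 and t[i] <= 5.0):
                continue
            for j in range(120):
                if j != i and (t[j] > t[i] or (c[j] == 2 and t[j] <= t[i])):
                    den += 1
                    num += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
        assert cm.value == pytest.approx(num / den, abs=1e-12)

    def test_perfect_ordering_without_censoring_is_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([1, 1, 1, 2])
        r = np.array([0.9, 0.8, 0.7, 0.1])
        assert ipcw_c_index(t, c, r, 10.0).value == 1.0


class TestCalibration:
    def test_affine_recovery_of_halved_slope(self):
        from pseudorisk import SimConfig, generate_cohort
        cfg = SimConfig(n_subjects=20_000, censor_rate=0.02,
                        region_sigma=0.0, seed=13)
        df = generate_cohort(cfg)
        pv = jackknife_pseudovalues(df["time"], df["cause"], 10.0).values
        p = np.clip(df["truth"].to_numpy(), 1e-6, 1 - 1e-6)
        doubled = -np.expm1(-np.exp(2 * np.log(-np.log1p(-p))))
        slope, _ = calibration_slope_citl(pv, doubled)
        assert slope.value == pytest.approx(0.5, abs=0.1)

    def test_constant_predictions_error_for_slope_but_not_citl(self):
        pv = np.array([0.1, 0.4, 0.2, 0.9, 0.0, 0.3] * 10)
        with pytest.raises(ValueError):
            calibration_slope_citl(pv, np.full(60, 0.3))
        cm = citl_only(pv, np.full(60, 0.3))
        assert np.isfinite(cm.value)


class TestSmoothedCurve:
    def test_identity_when_pseudovalues_equal_predictions(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(0.05, 0.9, 500)
        curve = smoothed_calibration_curve(p, p)
        inner = ~curve["extrapolated"]
        assert np.max(np.abs(curve.loc[inner, "observed"]
                             - curve.loc[inner, "predicted"])) < 0.02
        assert curve["density"].sum() == pytest.approx(1.0)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            smoothed_calibration_curve(np.linspace(0, 1, 20),
                                       np.linspace(0, 1, 20))


class TestDecisionCurve:
    def test_hand_enumerated_toy(self):
        # 10 subjects, single cause, no censoring: NB = TP/n - FP/n * odds
        time = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 9.5])
        cause = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        # administratively complete: recode "0" as observed event-free at 10
        time = np.where(cause == 0, 10.0, time)
        cause = np.where(cause == 0, 2, cause)   # alive -> competing placeholder
        risks = np.array([0.9, 0.8, 0.3, 0.6, 0.4, 0.1, 0.2, 0.05, 0.15, 0.25])
        thresholds = [0.1, 0.25, 0.5]
        dc = decision_curve(time, cause, risks, horizon=9.8,
                            thresholds=thresholds, competing=True)
        for k, pt in enumerate(thresholds):
            high = risks >= pt
            tp = np.sum(high & (cause == 1) & (time <= 9.8))
            fp = np.sum(high) - tp
            nb = tp / 10 - fp / 10 * pt / (1 - pt)
            assert dc.net_benefit[k] == pytest.approx(nb, abs=1e-12)

    def test_treat_none_is_zero_and_treat_all_limit(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(4, 300)
        c = rng.choice([0, 1, 2], 300)
        r = rng.random(300)
        dc = decision_curve(t, c, r, 5.0, thresholds=[1e-6, 0.2], competing=True)
        assert np.all(dc.treat_none == 0.0)
        from pseudorisk.nonparametric import aalen_johansen
        F = aalen_johansen(t, c, 1)(5.0)
        assert dc.treat_all[0] == pytest.approx(F, abs=1e-4)

    def test_km_variant_differs_under_competing_risks(self):
        rng = np.random.default_rng(16)
        t = rng.exponential(3, 400)
        c = rng.choice([1, 2], 400)
        r = rng.random(400)
        a = decision_curve(t, c, r, 5.0, thresholds=[0.3], competing=True)
        b = decision_curve(t, c, r, 5.0, thresholds=[0.3], competing=False)
        assert a.net_benefit[0] != b.net_benefit[0]

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            decision_curve([1.0], [1], [0.5], 5.0, thresholds=[0.0, 0.5])


class TestSubgroups:
    def test_single_group_equals_overall(self, small_cohort):
        df = small_cohort.reset_index(drop=True).copy()
        df["g"] = 1
        pred = df["truth"].to_numpy()
        table = subgroup_metrics(df, pred, "g")
        overall = ipcw_c_index(df["time"], df["cause"], pred, 10.0)
        assert table.loc[0, "c_index"] == pytest.approx(overall.value)

    def test_identical_groups_get_identical_metrics(self, small_cohort):
        half = small_cohort.head(400).reset_index(drop=True)
        df = pd.concat([half.assign(g=1), half.assign(g=2)],
                       ignore_index=True)
        pred = np.tile(half["truth"].to_numpy(), 2)
        table = subgroup_metrics(df, pred, "g").set_index("group")
        assert table.loc[1, "c_index"] == pytest.approx(table.loc[2, "c_index"])
        assert table.loc[1, "slope"] == pytest.approx(table.loc[2, "slope"])

    def test_small_groups_flagged(self, small_cohort):
        df = small_cohort.head(300).reset_index(drop=True).copy()
        df["g"] = np.where(df.index < 3, "tiny", "rest")
        table = subgroup_metrics(df, df["truth"].to_numpy(), "g")
        flagged = table.set_index("group").loc["tiny", "flag"]
        assert "not estimable" in flagged or flagged != ""

    def test_missing_grouping_errors(self, small_cohort):
        with pytest.raises(KeyError):
            subgroup_metrics(small_cohort, small_cohort["truth"].to_numpy(),
                             "nope")


def test_metrics_invariant_to_subject_order(small_cohort):
    df = small_cohort.head(400)
    pred = df["truth"].to_numpy()
    t, c = df["time"].to_numpy(), df["cause"].to_numpy()
    perm = np.random.default_rng(3).permutation(len(df))
    assert ipcw_c_index(t, c, pred, 10.0).value == pytest.approx(
        ipcw_c_index(t[perm], c[perm], pred[perm], 10.0).value, abs=1e-12)
    pv = jackknife_pseudovalues(t, c, 10.0).values
    s1, _ = calibration_slope_citl(pv, pred)
    s2, _ = calibration_slope_citl(pv[perm], pred[perm])
    assert s1.value == pytest.approx(s2.value, abs=1e-8)
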