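"""Discrimination, calibration, decision-analytic and crude-rate metrics
at the prediction horizon.

Discrimination uses Harrell's C over usable pairs (optionally with
inverse-probability-of-censoring weights under competing risks);
calibration is summarised by the calibration slope and
calibration-in-the-large from a pseudo-observation GLM on the
complementary log-log scale, so the same machinery serves the Cox model
(Kaplan-Meier failure pseudo-observations) and the competing-risks models
(CIF pseudo-observations).  Decision curves report net benefit against
treat-all and treat-none, with the event probability in the high-risk
group taken from the Aalen-Johansen CIF when competing risks are
acknowledged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .nonparametric import aalen_johansen, censoring_survival, kaplan_meier
from .pseudo import jackknife_pseudovalues

__all__ = [
    "ClusterMetric", "DecisionCurve", "RateResult", "crude_rate",
    "harrells_c", "ipcw_c_index", "calibration_slope_citl",
    "smoothed_calibration_curve", "decision_curve", "subgroup_metrics",
]

EPS = 1e-6  # clipping before link transforms (clipped ML output can be 0/1)


@dataclass
class ClusterMetric:
    kind: str                 # harrell_c | ipcw_c | slope | citl
    value: float
    se: float
    region: object = None
    imputation: object = None
    flag: str = ""


@dataclass
class RateResult:
    events: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float
    scale: float = 10_000.0


def crude_rate(events, person_years, scale=10_000.0, level=0.95) -> RateResult:
    """Crude event rate per ``scale`` person-years with a log-normal CI.

    CI = rate * exp(+-z / sqrt(events)); the log-symmetric construction
    implies ci_low * ci_high = rate**2 exactly.  Zero events give rate 0
    with an undefined (NaN) interval.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    rate = scale * events / person_years
    if events == 0:
        return RateResult(0, person_years, 0.0, np.nan, np.nan, scale)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = np.exp(z / np.sqrt(events))
    return RateResult(int(events), float(person_years), float(rate),
                      float(rate / half), float(rate * half), scale)


def _pairwise_c(time, case_mask, risk, horizon, weights_fn=None,
                competing_mask=None):
    """Chunked concordance sums; returns (num, den, influence per subject)."""
    n = len(time)
    num = 0.0
    den = 0.0
    a = np.zeros(n)   # per-subject concordant weight sums (symmetrised)
    b = np.zeros(n)   # per-subject comparable weight sums
    cases = np.flatnonzero(case_mask)
    for i in cases:
        later = time > time[i]
        if competing_mask is None:
            comp = later
        else:
            comp = later | (competing_mask & (time <= time[i]))
        comp[i] = False
        if not comp.any():
            continue
        w = np.ones(n) if weights_fn is None else weights_fn(i)
        w = np.where(comp, w, 0.0)
        conc = np.where(risk[i] > risk, 1.0, np.where(risk[i] == risk, 0.5, 0.0))
        cw = w * conc
        num += cw.sum()
        den += w.sum()
        a[i] += cw.sum()
        a += cw
        b[i] += w.sum()
        b += w
    return num, den, a, b


def _c_from_sums(num, den, a, b, kind, region=None, imputation=None, flag=""):
    if den == 0:
        raise ValueError("no usable pairs for the concordance index")
    c = num / den
    psi = a - c * b
    se = float(np.sqrt(np.sum(psi ** 2))) / den
    return ClusterMetric(kind, float(c), se, region, imputation, flag)


def harrells_c(time, event, risk, horizon, region=None,
               imputation=None) -> ClusterMetric:
    """Harrell's C at the horizon: usable pairs are (case i, j outlasting i).

    Cases are events within the horizon; ties in predicted risk count 1/2.
    The standard error is the pair-based (U-statistic influence) estimator.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    risk = np.asarray(risk, float)
    if not np.isfinite(risk).all():
        raise ValueError("risks must be finite")
    cases = event & (time <= horizon)
    num, den, a, b = _pairwise_c(time, cases, risk, horizon)
    return _c_from_sums(num, den, a, b, "harrell_c", region, imputation)


def ipcw_c_index(time, cause, risk, horizon, region=None,
                 imputation=None) -> ClusterMetric:
    """Truncated competing-risks concordance with IPCW pair weights.

    Cases are cause-1 events within the horizon.  Comparators are subjects
    still event-free at the case's time, weighted 1/G(t_i-)^2, and subjects
    with an earlier-or-equal competing event, weighted 1/(G(t_i-) G(t_j-)),
    where G is the Kaplan-Meier censoring survival.  Pairs whose weight is
    undefined because G has reached zero are dropped (flagged).
    """
    time = np.asarray(time, float)
    cause = np.asarray(cause, int)
    risk = np.asarray(risk, float)
    if not np.isfinite(risk).all():
        raise ValueError("risks must be finite")
    G = censoring_survival(time, cause)
    g_minus = np.asarray(G.left_limit(time), dtype=float)
    cases = (cause == 1) & (time <= horizon)
    competing = cause == 2
    flag = ""
    dropped = bool(np.any(g_minus[cases] <= 0))

    def weights(i):
        gi = g_minus[i]
        if gi <= 0:
            return np.zeros(len(time))
        w = np.full(len(time), 1.0 / gi ** 2)
        late_comp = competing & (time <= time[i])
        with np.errstate(divide="ignore"):
            wj = 1.0 / (gi * g_minus)
        w[late_comp] = np.where(g_minus[late_comp] > 0, wj[late_comp], 0.0)
        return w

    num, den, a, b = _pairwise_c(time, cases, risk, horizon,
                                 weights_fn=weights, competing_mask=competing)
    if dropped:
        flag = "pairs dropped where censoring survival reached zero"
    return _c_from_sums(num, den, a, b, "ipcw_c", region, imputation, flag)


def _cloglog(p):
    return np.log(-np.log1p(-p))


def calibration_slope_citl(pseudovalues, predictions, region=None,
                           imputation=None):
    """Calibration slope and calibration-in-the-large on the cloglog scale.

    Slope: coefficient of cloglog(p_hat) in a pseudo-observation GLM with
    cloglog link; CITL: intercept of the same family with cloglog(p_hat)
    as offset.  Ideal values are 1 and 0.  Robust (HC1) standard errors.
    """
    from .models import cloglog_family
    y = np.asarray(pseudovalues, float)
    p = np.clip(np.asarray(predictions, float), EPS, 1.0 - EPS)
    lp = _cloglog(p)
    fam = cloglog_family()
    if np.allclose(lp, lp[0]):
        raise ValueError("constant predictions: calibration slope undefined")
    X = sm.add_constant(lp)
    res = sm.GLM(y, X, family=fam).fit(cov_type="HC1", maxiter=200)
    slope = ClusterMetric("slope", float(res.params[1]), float(res.bse[1]),
                          region, imputation)
    res0 = sm.GLM(y, np.ones((len(y), 1)), family=fam, offset=lp).fit(
        cov_type="HC1", maxiter=200)
    citl = ClusterMetric("citl", float(res0.params[0]), float(res0.bse[0]),
                         region, imputation)
    return slope, citl


def citl_only(pseudovalues, predictions, region=None, imputation=None):
    """Calibration-in-the-large alone (estimable even for constant p_hat)."""
    from .models import cloglog_family
    y = np.asarray(pseudovalues, float)
    p = np.clip(np.asarray(predictions, float), EPS, 1.0 - EPS)
    fam = cloglog_family()
    res = sm.GLM(y, np.ones((len(y), 1)), family=fam,
                 offset=_cloglog(p)).fit(cov_type="HC1", maxiter=200)
    return ClusterMetric("citl", float(res.params[0]), float(res.bse[0]),
                         region, imputation)


def smoothed_calibration_curve(predictions, pseudovalues, grid=None,
                               frac=0.3) -> pd.DataFrame:
    """Running (lowess) smooth of pseudo-observations against predictions.

    Returns a table with the grid, the smoothed observed risk, an
    extrapolation flag outside the observed prediction range, and the
    histogram mass of predictions near each grid point.
    """
    p = np.asarray(predictions, float)
    y = np.asarray(pseudovalues, float)
    if len(p) < 50:
        raise ValueError("at least 50 subjects are required for smoothing")
    if grid is None:
        grid = np.linspace(np.quantile(p, 0.01), np.quantile(p, 0.99), 50)
    grid = np.asarray(grid, float)
    from statsmodels.nonparametric.smoothers_lowess import lowess
    sm_xy = lowess(y, p, frac=frac, it=0, xvals=grid)
    extrap = (grid < p.min()) | (grid > p.max())
    edges = np.concatenate(([-np.inf],
                            (grid[1:] + grid[:-1]) / 2.0, [np.inf]))
    hist = np.histogram(p, bins=edges)[0] / len(p)
    return pd.DataFrame({"predicted": grid, "observed": sm_xy,
                         "extrapolated": extrap, "density": hist})


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = None
    competing_risks: bool = True
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.treat_none is None:
            self.treat_none = np.zeros_like(np.asarray(self.thresholds, float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "net_benefit": self.net_benefit,
            "treat_all": self.treat_all, "treat_none": self.treat_none})


def _event_probability(time, cause, horizon, competing):
    if len(time) == 0:
        return np.nan
    if competing:
        return float(aalen_johansen(time, cause, 1)(horizon))
    return 1.0 - float(kaplan_meier(time, cause == 1)(horizon))


def decision_curve(time, cause, risks, horizon, thresholds=None,
                   competing=True) -> DecisionCurve:
    """Net benefit across threshold probabilities.

    NB(p_t) = P(p_hat >= p_t) * [F_high - (1 - F_high) p_t / (1 - p_t)]
    with F_high the event probability by the horizon among the high-risk
    group (Aalen-Johansen CIF when competing risks are acknowledged,
    Kaplan-Meier failure otherwise).  Treat-all uses the whole-sample F;
    treat-none is identically zero.
    """
    time = np.asarray(time, float)
    cause = np.asarray(cause, int)
    risks = np.asarray(risks, float)
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.501, 0.01), 4)
    thresholds = np.asarray(thresholds, float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    F_all = _event_probability(time, cause, horizon, competing)
    nb = np.zeros(len(thresholds))
    ta = np.zeros(len(thresholds))
    flags = []
    for k, pt in enumerate(thresholds):
        odds = pt / (1.0 - pt)
        ta[k] = F_all - (1.0 - F_all) * odds
        high = risks >= pt
        if not high.any():
            flags.append(f"no subjects above threshold {pt:.3g}")
            continue
        F_high = _event_probability(time[high], cause[high], horizon, competing)
        nb[k] = high.mean() * (F_high - (1.0 - F_high) * odds)
    return DecisionCurve(thresholds, nb, ta, competing_risks=competing,
                         flags=flags)


def subgroup_metrics(cohort: pd.DataFrame, predictions, grouping,
                     horizon=10.0, target="cif_cause1",
                     min_events=2) -> pd.DataFrame:
    """Per-group C / slope / CITL with small-group flags.

    Pseudo-observations are recomputed within each group so calibration is
    judged against the group's own nonparametric risk.  Groups with fewer
    than ``min_events`` cause-1 events are flagged not estimable.
    """
    if grouping not in cohort.columns:
        raise KeyError(f"grouping variable {grouping!r} not present")
    predictions = np.asarray(predictions, float)
    rows = []
    for gval, idx in cohort.groupby(grouping, sort=True).groups.items():
        sub = cohort.loc[idx]
        p = predictions[cohort.index.get_indexer(idx)]
        t = sub["time"].to_numpy()
        c = sub["cause"].to_numpy()
        n_events = int((c == 1).sum())
        if n_events < min_events or len(sub) < 3:
            rows.append({"group": gval, "n": len(sub), "events": n_events,
                         "c_index": np.nan, "slope": np.nan, "citl": np.nan,
                         "flag": "not estimable: too few events"})
            continue
        try:
            cm = (ipcw_c_index(t, c, p, horizon) if target == "cif_cause1"
                  else harrells_c(t, c == 1, p, horizon))
            pv = jackknife_pseudovalues(t, c, horizon, target).values
            try:
                slope, citl = calibration_slope_citl(pv, p)
                s_val, citl_val = slope.value, citl.value
            except ValueError:
                s_val = np.nan
                citl_val = citl_only(pv, p).value
            rows.append({"group": gval, "n": len(sub), "events": n_events,
                         "c_index": cm.value, "slope": s_val,
                         "citl": citl_val, "flag": ""})
        except ValueError as exc:
            rows.append({"group": gval, "n": len(sub), "events": n_events,
                         "c_index": np.nan, "slope": np.nan, "citl": np.nan,
                         "flag": str(exc)})
    return pd.DataFrame(rows)
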