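"""The four model-building strategies as scikit-learn-style estimators.

Every estimator exposes ``fit``/``predict`` with predictions on the 10-year
event-probability scale in [0, 1]:

* :class:`CoxRiskModel` — proportional-hazards partial likelihood (Efron
  ties) with clustered sandwich standard errors, competing deaths treated
  as censored; risk = 1 - S0 ** exp(X beta) with continuous predictors
  centred at their means and binary predictors at zero.
* :class:`PseudoCloglogRisk` — quasi-likelihood GLM of CIF
  pseudo-observations with a complementary log-log link and robust
  sandwich errors; coefficients act on the subdistribution scale and
  risk = 1 - exp(-exp(X beta)).
* :class:`PseudoXGBRisk` — gradient-boosted trees with a squared-error
  objective on pseudo-observations; predictions clipped to [0, 1].
* :class:`PseudoMLPRisk` — a feed-forward network on min-max-scaled
  inputs with the same pseudo-observation target; predictions clipped.

The second half of the module handles multiply imputed data: per-imputation
fits pooled by Rubin's rules, the magnitude-and-significance predictor
selection rule, pooled baseline survival on the cumulative-hazard scale,
and a JSON-serialisable pooled regression model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import DomainWarning

# the Gaussian-variance / cloglog-link combination is deliberate (see
# cloglog_family); statsmodels flags it because the link range is not R
warnings.simplefilter("ignore", DomainWarning)
from scipy import stats
from sklearn.base import BaseEstimator

from .design import build_design
from .fp import FPSpec
from .impute import rubin_pool
from .nn import FeedForwardNet

__all__ = [
    "CoxRiskModel", "PseudoCloglogRisk", "PseudoXGBRisk", "PseudoMLPRisk",
    "pool_coefficients", "select_predictors", "PooledRegressionModel",
    "fit_pooled_cox", "fit_pooled_cloglog",
]


class _GaussianCLogLog(sm.families.Gaussian):
    """Gaussian working variance with a complementary log-log mean link."""

    links = list(sm.families.Gaussian.links) + [sm.families.links.CLogLog]


def cloglog_family(working_variance="gaussian"):
    """GLM family for pseudo-observation regression on the cloglog scale.

    The mean model 1 - exp(-exp(X beta)) is shared; only the working
    variance differs.  The Gaussian choice (default) keeps the quasi-score
    bounded when pseudo-observations fall far outside [0, 1] — the
    binomial variance mu(1-mu) diverges as fitted values approach 1, which
    makes the fit degenerate whenever a covariate cell's pseudo-observation
    mean exceeds 1 (common under heavy censoring near the horizon).  Both
    working variances give consistent coefficients for the same mean model;
    sandwich standard errors remain valid either way.
    """
    if working_variance == "gaussian":
        return _GaussianCLogLog(link=sm.families.links.CLogLog())
    if working_variance == "binomial":
        return sm.families.Binomial(link=sm.families.links.CLogLog())
    raise ValueError("working_variance must be 'gaussian' or 'binomial'")


def _extract_surv(y):
    """Accept a (time, event) DataFrame / structured array / tuple."""
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy().astype(bool)
    if isinstance(y, np.ndarray) and y.dtype.names:
        return y["time"].astype(float), y["event"].astype(bool)
    t, e = y
    return np.asarray(t, float), np.asarray(e).astype(bool)


class CoxRiskModel(BaseEstimator):
    """Cox proportional hazards model for 10-year event probability.

    Parameters
    ----------
    horizon : float
        Prediction horizon in years.
    continuous_cols : list of str, optional
        Design columns centred at their means; all other columns are
        treated as binary and centred at zero.
    penalizer : float
        Small ridge penalty passed to the partial-likelihood optimiser.
    """

    def __init__(self, horizon=10.0, continuous_cols=None, penalizer=0.0):
        self.horizon = horizon
        self.continuous_cols = continuous_cols
        self.penalizer = penalizer

    def fit(self, X, y, cluster=None):
        from lifelines import CoxPHFitter
        X = pd.DataFrame(X).reset_index(drop=True)
        time, event = _extract_surv(y)
        if event.sum() == 0:
            raise ValueError("no events observed; cannot fit a Cox model")
        n_params = X.shape[1]
        if event.sum() < 10 * n_params:
            import warnings
            warnings.warn("fewer than 10 events per parameter", stacklevel=2)
        cont = [c for c in (self.continuous_cols or []) if c in X.columns]
        centers = pd.Series(0.0, index=X.columns)
        centers[cont] = X[cont].mean()
        Xc = X - centers
        df = Xc.copy()
        df["__T"] = time
        df["__E"] = event.astype(int)
        kw = {}
        if cluster is not None:
            df["__cl"] = np.asarray(cluster)
            kw["cluster_col"] = "__cl"
        cph = CoxPHFitter(penalizer=self.penalizer)
        cph.fit(df, duration_col="__T", event_col="__E", **kw)
        self.coef_ = cph.params_.copy()
        self.se_ = cph.standard_errors_.copy()
        self.centers_ = centers
        self.log_likelihood_ = float(cph.log_likelihood_)
        # Breslow baseline cumulative hazard at the centred covariates
        lp = Xc.to_numpy() @ self.coef_.to_numpy()
        self.baseline_cumhaz_ = _breslow_cumhaz(time, event, lp, self.horizon)
        self.baseline_survival_ = float(np.exp(-self.baseline_cumhaz_))
        self.n_events_ = int(event.sum())
        return self

    def linear_predictor(self, X):
        X = pd.DataFrame(X)[self.coef_.index]
        return (X - self.centers_).to_numpy() @ self.coef_.to_numpy()

    def predict(self, X):
        """Predicted event probability 1 - S0 ** exp(X beta) in [0, 1]."""
        risk = 1.0 - self.baseline_survival_ ** np.exp(self.linear_predictor(X))
        return np.clip(risk, 0.0, 1.0)


def _breslow_cumhaz(time, event, lp, horizon):
    order = np.argsort(time, kind="mergesort")
    t, e, z = time[order], event[order], np.exp(lp[order])
    rev_cum = np.cumsum(z[::-1])[::-1]       # risk-set sums
    h0 = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        if t[i] <= horizon:
            d = int(e[i:j].sum())
            if d > 0:
                h0 += d / rev_cum[i]
        i = j
    return float(h0)


class PseudoCloglogRisk(BaseEstimator):
    """Pseudo-observation GLM with complementary log-log link.

    Fit by quasi-likelihood IRLS (the binomial working variance) with
    sandwich standard errors, since pseudo-observations are neither
    independent nor confined to [0, 1].
    """

    def __init__(self, cov_type="HC1", add_intercept=True, maxiter=200,
                 working_variance="gaussian"):
        self.cov_type = cov_type
        self.add_intercept = add_intercept
        self.maxiter = maxiter
        self.working_variance = working_variance

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[1] == 0 and not self.add_intercept:
            raise ValueError("no predictors and no intercept")
        if np.allclose(y, y[0]):
            raise ValueError("degenerate input: all pseudo-observations equal")
        Xd = sm.add_constant(X, has_constant="add") if self.add_intercept else X
        mod = sm.GLM(y, Xd, family=cloglog_family(self.working_variance))
        res = mod.fit(maxiter=self.maxiter, cov_type=self.cov_type)
        if not res.converged:
            # IRLS can oscillate within a tiny band; polish with a direct
            # quasi-likelihood optimisation started from the IRLS iterate
            start = np.asarray(res.params, dtype=float)
            if not np.isfinite(start).all():
                start = np.zeros(Xd.shape[1])
                if self.add_intercept:
                    mean_clip = np.clip(np.mean(y), 1e-4, 1.0 - 1e-4)
                    start[0] = np.log(-np.log1p(-mean_clip))
            res = mod.fit(method="lbfgs", maxiter=10 * self.maxiter,
                          start_params=start, cov_type=self.cov_type)
        if not np.isfinite(res.params).all() or np.abs(res.params).max() > 1e8:
            raise RuntimeError("cloglog fit did not converge")
        self.result_ = res
        self.coef_ = res.params.copy()
        self.se_ = res.bse.copy()
        self.columns_ = list(Xd.columns)
        return self

    def linear_predictor(self, X):
        X = pd.DataFrame(X)
        if self.add_intercept:
            X = sm.add_constant(X, has_constant="add")
        return X[self.columns_].to_numpy() @ self.coef_.to_numpy()

    def predict(self, X):
        """1 - exp(-exp(X beta)), strictly inside (0, 1)."""
        return -np.expm1(-np.exp(self.linear_predictor(X)))


class PseudoXGBRisk(BaseEstimator):
    """Gradient-boosted trees regressing pseudo-observations.

    Hyperparameter names and default search ranges follow the usual tree
    booster: depth, learning rate, subsampling, L1/L2/complexity penalties
    and column sampling per tree/level.  Runs the CPU histogram algorithm.
    """

    def __init__(self, n_rounds=100, max_depth=3, eta=0.05, subsample=0.5,
                 alpha=0.0, gamma=0.0, reg_lambda=1.0, colsample_bytree=0.8,
                 colsample_bylevel=0.8, seed=0):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.eta = eta
        self.subsample = subsample
        self.alpha = alpha
        self.gamma = gamma
        self.reg_lambda = reg_lambda
        self.colsample_bytree = colsample_bytree
        self.colsample_bylevel = colsample_bylevel
        self.seed = seed

    def fit(self, X, y):
        import xgboost as xgb
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        self.model_ = xgb.XGBRegressor(
            objective="reg:squarederror", tree_method="hist",
            n_estimators=int(self.n_rounds), max_depth=int(self.max_depth),
            learning_rate=self.eta, subsample=self.subsample,
            reg_alpha=self.alpha, gamma=self.gamma, reg_lambda=self.reg_lambda,
            colsample_bytree=self.colsample_bytree,
            colsample_bylevel=self.colsample_bylevel,
            random_state=int(self.seed) % (2 ** 31), n_jobs=1, verbosity=0)
        self.model_.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
        return self

    def predict_raw(self, X):
        X = pd.DataFrame(X)[self.columns_]
        return self.model_.predict(X.to_numpy(dtype=float)).astype(float)

    def predict(self, X):
        return np.clip(self.predict_raw(X), 0.0, 1.0)


class PseudoMLPRisk(BaseEstimator):
    """Feed-forward network regressing pseudo-observations.

    Inputs are min-max scaled to [0, 1] with parameters learned on the
    training data; predictions are clipped to [0, 1].
    """

    def __init__(self, n_hidden_layers=2, n_units=30, learning_rate=0.01,
                 epochs=30, batch_size=1024, seed=0):
        self.n_hidden_layers = n_hidden_layers
        self.n_units = n_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        arr = X.to_numpy(dtype=float)
        self.min_ = arr.min(axis=0)
        rng = arr.max(axis=0) - self.min_
        self.range_ = np.where(rng > 0, rng, 1.0)
        self.net_ = FeedForwardNet(
            n_hidden_layers=self.n_hidden_layers, n_units=self.n_units,
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.seed)
        self.net_.fit((arr - self.min_) / self.range_, np.asarray(y, float))
        return self

    def predict_raw(self, X):
        X = pd.DataFrame(X)[self.columns_]
        arr = (X.to_numpy(dtype=float) - self.min_) / self.range_
        return self.net_.predict(arr)

    def predict(self, X):
        return np.clip(self.predict_raw(X), 0.0, 1.0)


# ---------------------------------------------------------------------------
# multiple-imputation pooling, predictor selection, pooled regression models
# ---------------------------------------------------------------------------

def pool_coefficients(fits, meta) -> pd.DataFrame:
    """Rubin-pool coefficient vectors from per-imputation fits.

    ``fits`` is a list of estimators exposing ``coef_`` and ``se_`` over a
    common term index; ``meta`` maps terms to variables/types.  Returns a
    table with pooled estimate, se, Barnard-Rubin df and two-sided p-value.
    """
    terms = fits[0].coef_.index
    rows = []
    for term in terms:
        est = np.array([f.coef_[term] for f in fits])
        var = np.array([f.se_[term] ** 2 for f in fits])
        if len(fits) == 1:
            pooled_est, pooled_se, df = est[0], np.sqrt(var[0]), np.inf
        else:
            p = rubin_pool(est, var)
            pooled_est, pooled_se, df = p.estimate, p.se, p.df
        pval = 2.0 * stats.t.sf(abs(pooled_est) / pooled_se, min(df, 1e12))
        rows.append((term, pooled_est, pooled_se, df, pval))
    table = pd.DataFrame(rows, columns=["term", "estimate", "se", "df", "p"])
    return table.merge(meta, on="term", how="left")


def select_predictors(pooled_table: pd.DataFrame, hr_low=0.9, hr_high=1.1,
                      p_categorical=0.01, p_continuous=0.01) -> list:
    """Magnitude-and-significance predictor selection.

    Binary or multilevel categorical predictors are kept when any level has
    an exponentiated coefficient > ``hr_high`` or < ``hr_low`` at
    P < ``p_categorical``; continuous variables (all their FP terms) and
    interactions are kept at P < ``p_continuous``.  Multilevel variables
    enter whole if any level qualifies.
    """
    keep = []
    for var, grp in pooled_table.groupby("variable", sort=False):
        vtype = grp["type"].iloc[0]
        if vtype in ("binary", "categorical"):
            hr = np.exp(grp["estimate"])
            ok = ((hr > hr_high) | (hr < hr_low)) & (grp["p"] < p_categorical)
        else:  # continuous or interaction
            ok = grp["p"] < p_continuous
        if ok.any():
            keep.append(var)
    return keep


@dataclass
class PooledRegressionModel:
    """A Rubin-pooled Cox or cloglog model with everything needed to predict."""

    kind: str                      # "cox" or "cloglog"
    coef: pd.Series
    se: pd.Series
    predictors: list
    fp_specs: dict = field(default_factory=dict)
    centers: pd.Series = None      # cox only
    baseline_survival: float = None  # cox only: S0 at the horizon
    horizon: float = 10.0
    coef_table: pd.DataFrame = None

    def _design(self, df):
        X, _ = build_design(df, self.predictors, self.fp_specs)
        return X

    def linear_predictor(self, df):
        X = self._design(df)
        cols = [c for c in self.coef.index if c != "const"]
        lp = X[cols].to_numpy() @ self.coef[cols].to_numpy()
        if self.kind == "cox":
            lp -= self.centers[cols].to_numpy() @ self.coef[cols].to_numpy()
        else:
            lp = lp + self.coef.get("const", 0.0)
        return lp

    def predict(self, df):
        lp = self.linear_predictor(df)
        if self.kind == "cox":
            return np.clip(1.0 - self.baseline_survival ** np.exp(lp), 0.0, 1.0)
        return -np.expm1(-np.exp(lp))

    # -- text serialisation -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "coef": {k: float(v) for k, v in self.coef.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "predictors": list(self.predictors),
            "fp_specs": {v: {"powers": list(s.powers), "shift": s.shift,
                             "scale": s.scale} for v, s in self.fp_specs.items()},
            "centers": None if self.centers is None else
                       {k: float(v) for k, v in self.centers.items()},
            "baseline_survival": self.baseline_survival,
            "horizon": self.horizon,
        }
        return json.dumps(payload, indent=1)   # order preserved so reloaded
        # coefficient vectors sum in the same sequence (bit-identical risk)

    @classmethod
    def from_json(cls, text: str) -> "PooledRegressionModel":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            coef=pd.Series(d["coef"]),
            se=pd.Series(d["se"]),
            predictors=d["predictors"],
            fp_specs={v: FPSpec(v, tuple(s["powers"]), s["shift"], s["scale"])
                      for v, s in d["fp_specs"].items()},
            centers=None if d["centers"] is None else pd.Series(d["centers"]),
            baseline_survival=d["baseline_survival"],
            horizon=d["horizon"])


def fit_pooled_cox(datasets, predictors, fp_specs=None, horizon=10.0,
                   cluster_col=None, penalizer=0.0):
    """Fit a Cox model in every imputed dataset and Rubin-pool the results.

    Competing deaths (cause 2) are treated as censored.  The baseline
    survival at the horizon is pooled on the cumulative-hazard scale:
    S0 = exp(-mean_j H0_j).
    """
    fits, metas = [], None
    for df in datasets:
        X, meta = build_design(df, predictors, fp_specs)
        metas = meta
        cont = meta.loc[meta["type"] == "continuous", "term"].tolist()
        y = pd.DataFrame({"time": df["time"].to_numpy(),
                          "event": (df["cause"] == 1).to_numpy()})
        cluster = df[cluster_col].to_numpy() if cluster_col else None
        fits.append(CoxRiskModel(horizon=horizon, continuous_cols=cont,
                                 penalizer=penalizer).fit(X, y, cluster=cluster))
    table = pool_coefficients(fits, metas)
    coef = pd.Series(table["estimate"].to_numpy(), index=table["term"])
    se = pd.Series(table["se"].to_numpy(), index=table["term"])
    h0 = np.mean([f.baseline_cumhaz_ for f in fits])
    centers = sum(f.centers_ for f in fits) / len(fits)
    model = PooledRegressionModel(
        kind="cox", coef=coef, se=se, predictors=list(predictors),
        fp_specs=dict(fp_specs or {}), centers=centers,
        baseline_survival=float(np.exp(-h0)), horizon=horizon,
        coef_table=table)
    return model, fits


def fit_pooled_cloglog(datasets, pseudovalues, predictors, fp_specs=None,
                       horizon=10.0):
    """Pseudo-observation cloglog regression, Rubin-pooled across imputations.

    ``pseudovalues`` is shared across imputations (follow-up is complete);
    only the imputed covariates differ between fits.
    """
    fits, metas = [], None
    for df in datasets:
        X, meta = build_design(df, predictors, fp_specs)
        metas = meta
        fits.append(PseudoCloglogRisk().fit(X, pseudovalues))
    meta = pd.concat([pd.DataFrame([("const", "const", "intercept")],
                                   columns=["term", "variable", "type"]),
                      metas], ignore_index=True)
    table = pool_coefficients(fits, meta)
    coef = pd.Series(table["estimate"].to_numpy(), index=table["term"])
    se = pd.Series(table["se"].to_numpy(), index=table["term"])
    model = PooledRegressionModel(
        kind="cloglog", coef=coef, se=se, predictors=list(predictors),
        fp_specs=dict(fp_specs or {}), horizon=horizon, coef_table=table)
    return model, fits
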