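"""Random-effects pooling of cluster-level performance metrics.

Region-level estimates from internal-external cross-validation are pooled
with DerSimonian-Laird heterogeneity and the Hartung-Knapp-Sidik-Jonkman
variance adjustment: the pooled variance is the weighted mean squared
deviation q / ((k-1) sum w) with w = 1/(se^2 + tau^2), and confidence
limits use the t distribution with k-1 degrees of freedom.  The 95%
prediction interval — the range of performance expected in a new cluster —
uses t with k-2 degrees of freedom and variance tau^2 + se_pooled^2.

Meta-regression decomposes the heterogeneity: the method-of-moments
residual tau^2 generalises DerSimonian-Laird, R^2 is the percentage of
tau^2 explained by cluster covariates (clipped to [0, 100]), and the
residual I^2 comes from the residual Q statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .impute import rubin_pool
from .metrics import ClusterMetric

__all__ = ["MetaResult", "MetaRegResult", "hksj_random_effects",
           "meta_regression", "pool_metric_over_imputations"]


@dataclass
class MetaResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pi_low: float
    pi_high: float
    tau2: float
    i2: float
    k: int
    q: float = np.nan

    def to_dict(self):
        return {k: getattr(self, k) for k in
                ("estimate", "se", "ci_low", "ci_high", "pi_low", "pi_high",
                 "tau2", "i2", "k")}


@dataclass
class MetaRegResult:
    covariates: list
    coef_table: pd.DataFrame
    tau2: float
    tau2_null: float
    r2: float
    residual_i2: float
    k: int


def _dl_tau2(y, v):
    """DerSimonian-Laird moment estimator of between-cluster variance."""
    w = 1.0 / v
    mu_fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    k = len(y)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return tau2, q


def hksj_random_effects(estimates, ses, level=0.95) -> MetaResult:
    """Random-effects pooling with the Hartung-Knapp-Sidik-Jonkman method.

    Requires k >= 2; the prediction interval needs k >= 3 and is NaN
    otherwise.  With all estimates equal the heterogeneity tau^2 and I^2
    are zero and the pooled value is the common value.
    """
    y = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("meta-analysis requires at least two clusters")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    v = se ** 2
    tau2, q = _dl_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    # HKSJ: empirically scaled variance, t-based confidence limits
    qstat = float(np.sum(w * (y - mu) ** 2) / (k - 1))
    se_pooled = float(np.sqrt(qstat / np.sum(w)))
    alpha = 1.0 - level
    t_ci = stats.t.ppf(1.0 - alpha / 2.0, k - 1)
    ci_low, ci_high = mu - t_ci * se_pooled, mu + t_ci * se_pooled
    if k >= 3:
        t_pi = stats.t.ppf(1.0 - alpha / 2.0, k - 2)
        half = t_pi * np.sqrt(tau2 + se_pooled ** 2)
        pi_low, pi_high = mu - half, mu + half
    else:
        pi_low = pi_high = np.nan
    i2 = max(0.0, 100.0 * (q - (k - 1)) / q) if q > 0 else 0.0
    return MetaResult(mu, se_pooled, float(ci_low), float(ci_high),
                      float(pi_low), float(pi_high), float(tau2),
                      float(i2), k, q)


def meta_regression(estimates, ses, covariates: pd.DataFrame,
                    level=0.95) -> MetaRegResult:
    """Weighted meta-regression with moment-based residual heterogeneity.

    ``covariates`` holds one row per cluster.  R^2 compares the residual
    tau^2 against the intercept-only (DerSimonian-Laird) tau^2 and is
    clipped to [0, 100]; when the model tau^2 exceeds the null tau^2 the
    explained share is reported as 0, not negative.
    """
    y = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    v = se ** 2
    X = pd.DataFrame(covariates).copy()
    names = list(X.columns)
    Xmat = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    k, p = Xmat.shape
    if k <= p + 1:
        raise ValueError("need more clusters than covariates plus two")
    if np.linalg.matrix_rank(Xmat) < p:
        raise ValueError("collinear covariates in meta-regression")

    # method-of-moments residual tau^2: E[Q_E] = (k - p) + tau2 tr(P)
    W = np.diag(1.0 / v)
    XtWX_inv = np.linalg.inv(Xmat.T @ W @ Xmat)
    P = W - W @ Xmat @ XtWX_inv @ Xmat.T @ W
    q_e = float(y @ P @ y)
    tr_p = float(np.trace(P))
    tau2 = max(0.0, (q_e - (k - p)) / tr_p) if tr_p > 0 else 0.0

    tau2_null, _ = _dl_tau2(y, v)
    r2 = 0.0 if tau2_null <= 0 else float(
        np.clip(100.0 * (1.0 - tau2 / tau2_null), 0.0, 100.0))
    residual_i2 = max(0.0, 100.0 * (q_e - (k - p)) / q_e) if q_e > 0 else 0.0

    # refit with random-effects weights and HKSJ-type scaling
    w_star = 1.0 / (v + tau2)
    Ws = np.diag(w_star)
    cov_unscaled = np.linalg.inv(Xmat.T @ Ws @ Xmat)
    beta = cov_unscaled @ Xmat.T @ Ws @ y
    resid = y - Xmat @ beta
    scale = max(float(resid @ Ws @ resid) / (k - p), 1e-12)
    cov = cov_unscaled * scale
    bse = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.5 + level / 2.0, k - p)
    pvals = 2.0 * stats.t.sf(np.abs(beta) / bse, k - p)
    table = pd.DataFrame({
        "term": ["intercept"] + names, "estimate": beta, "se": bse,
        "ci_low": beta - tcrit * bse, "ci_high": beta + tcrit * bse,
        "p": pvals})
    return MetaRegResult(names, table, float(tau2), float(tau2_null),
                         r2, float(residual_i2), k)


def pool_metric_over_imputations(metrics) -> list:
    """Rubin's-rules pooling of per-imputation ClusterMetrics by cluster.

    ``metrics`` is an iterable of :class:`ClusterMetric` with ``region``
    and ``imputation`` set.  Returns one pooled ClusterMetric per
    (kind, region), ready for meta-analysis.
    """
    frame = pd.DataFrame([{"kind": m.kind, "region": m.region,
                           "imputation": m.imputation, "value": m.value,
                           "se": m.se} for m in metrics])
    if frame["imputation"].isna().any():
        raise ValueError("every metric needs an imputation index")
    pooled = []
    for (kind, region), grp in frame.groupby(["kind", "region"], sort=True):
        if grp["imputation"].duplicated().any():
            raise ValueError(f"duplicate imputation indices for {kind}/{region}")
        if len(grp) < 2:
            raise ValueError("need at least two imputations per cluster")
        p = rubin_pool(grp["value"].to_numpy(), grp["se"].to_numpy() ** 2)
        pooled.append(ClusterMetric(kind, p.estimate, p.se, region=region))
    return pooled
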