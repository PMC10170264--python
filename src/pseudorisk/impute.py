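"""Chained-equations multiple imputation and Rubin's-rules pooling.

The imputation model for every incomplete variable conditions on all other
candidate predictors, the endpoint indicator (the cause code as a factor),
the treatment auxiliaries, the per-subject Nelson-Aalen cumulative hazard
value, and the period of cohort entry.  BMI is imputed on the natural-log
scale and exponentiated back.  Draws use predictive mean matching (5
donors) for every incomplete variable: donor-based draws automatically
return valid levels for categorical variables.

The machine-learning strategies consume the imputations stacked into one
long table with an ``imputation`` index column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.imputation.mice import MICEData

from .nonparametric import nelson_aalen

__all__ = ["ImputationStack", "PooledEstimate", "mice_impute", "rubin_pool",
           "stack_imputations"]

#: columns never entered into the chained-equation system
_NON_MODEL_COLS = ("id", "time", "truth", "entry")


@dataclass
class ImputationStack:
    """``m`` completed copies of one cohort plus the seed ledger."""

    datasets: list
    seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of one scalar across imputations."""

    estimate: float
    within_var: float
    between_var: float
    m: int
    df_com: float = field(default=np.inf)

    @property
    def total_var(self) -> float:
        return self.within_var + (1.0 + 1.0 / self.m) * self.between_var

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    @property
    def df(self) -> float:
        """Barnard-Rubin small-sample degrees of freedom."""
        T = self.total_var
        if T == 0 or self.between_var == 0:
            return np.inf
        lam = (1.0 + 1.0 / self.m) * self.between_var / T
        df_old = (self.m - 1) / lam ** 2
        if np.isinf(self.df_com):
            return df_old
        df_obs = ((self.df_com + 1.0) / (self.df_com + 3.0)
                  * self.df_com * (1.0 - lam))
        return 1.0 / (1.0 / df_old + 1.0 / df_obs)

    def ci(self, level=0.95):
        tcrit = stats.t.ppf(0.5 + level / 2.0, min(self.df, 1e12))
        return (self.estimate - tcrit * self.se, self.estimate + tcrit * self.se)


def rubin_pool(estimates, variances, df_com=np.inf) -> PooledEstimate:
    """Pool per-imputation estimates and variances by Rubin's rules."""
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if estimates.size < 2:
        raise ValueError("Rubin's rules require at least two imputations")
    if np.any(variances < 0):
        raise ValueError("variances must be non-negative")
    m = estimates.size
    return PooledEstimate(
        estimate=float(estimates.mean()),
        within_var=float(variances.mean()),
        between_var=float(estimates.var(ddof=1)),
        m=m, df_com=df_com)


def _prepare(cohort: pd.DataFrame, horizon: float):
    """Numeric working frame with auxiliaries for the chained equations."""
    work = cohort.drop(columns=[c for c in _NON_MODEL_COLS if c in cohort],
                       errors="ignore").copy()
    na = nelson_aalen(cohort["time"], cohort["cause"] == 1)
    work["nelson_aalen"] = na(np.minimum(cohort["time"].to_numpy(), horizon))
    work["endpoint_1"] = (cohort["cause"] == 1).astype(float)
    work["endpoint_2"] = (cohort["cause"] == 2).astype(float)
    work = work.drop(columns=["cause"])
    if "bmi" in work:
        work["bmi"] = np.log(work["bmi"])
    cat_maps = {}
    for col in work.columns:
        if work[col].dtype == object:
            levels = sorted(work[col].dropna().unique())
            cat_maps[col] = levels
            work[col] = work[col].map({v: i for i, v in enumerate(levels)})
    return work.astype(float), cat_maps


def _restore(completed: pd.DataFrame, cohort: pd.DataFrame, cat_maps):
    out = cohort.copy()
    for col in cohort.columns:
        if col not in completed:
            continue
        vals = completed[col]
        if col == "bmi":
            vals = np.exp(vals)
        if col in cat_maps:
            vals = vals.round().astype(int).map(dict(enumerate(cat_maps[col])))
        elif pd.api.types.is_integer_dtype(cohort[col].dropna()) or col in (
                "stage", "grade", "er", "pr", "her2", "smoking"):
            vals = vals.round().astype(int)
        out[col] = np.asarray(vals)
    return out


def mice_impute(cohort: pd.DataFrame, m=5, n_cycles=10, seed=0,
                horizon=10.0) -> ImputationStack:
    """Multiple imputation by chained equations with PMM draws.

    Parameters
    ----------
    cohort : DataFrame
        One row per subject with possibly missing covariates; ``time`` and
        ``cause`` must be complete.
    m : int
        Number of imputations (>= 2).
    n_cycles : int
        Gibbs cycles between retained datasets.
    """
    if m < 2:
        raise ValueError("at least two imputations are required")
    incomplete = [c for c in cohort.columns if cohort[c].isna().any()]
    fully_missing = [c for c in incomplete if cohort[c].isna().all()]
    if fully_missing:
        raise ValueError(f"variables with no observed values: {fully_missing}")
    if not incomplete:
        return ImputationStack([cohort.copy() for _ in range(m)], seed)

    work, cat_maps = _prepare(cohort, horizon)
    datasets = []
    # MICEData draws via the numpy global state; scope it locally
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2 ** 31))
        md = MICEData(work, k_pmm=5)
        for _ in range(m):
            md.update_all(n_cycles)
            datasets.append(_restore(md.data.copy(), cohort, cat_maps))
    finally:
        np.random.set_state(state)
    return ImputationStack(datasets, seed)


def stack_imputations(stack: ImputationStack) -> pd.DataFrame:
    """Stack completed datasets into one long table (m x n rows)."""
    parts = []
    for j, df in enumerate(stack.datasets, start=1):
        part = df.copy()
        part.insert(0, "imputation", j)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
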