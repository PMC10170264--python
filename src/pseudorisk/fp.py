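"""Fractional-polynomial bases and deviance-based term selection.

A fractional polynomial of degree 1 or 2 transforms a positive variable x
through powers drawn from {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, where power 0
denotes log x and a repeated power p adds the column x**p * log x.  The
best degree-1 and degree-2 specifications are found by deviance over the
fixed power set within the relevant model family (Cox partial likelihood
or pseudo-observation cloglog GLM), with a closed test at alpha = 0.05
deciding whether the non-linear terms earn their keep over a linear term.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["FP_POWERS", "FPSpec", "fp_basis", "select_fractional_polynomial"]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPSpec:
    """A fitted fractional-polynomial transform for one variable."""

    variable: str
    powers: tuple
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if not 1 <= len(self.powers) <= 2:
            raise ValueError("one or two powers are permitted")
        if any(p not in FP_POWERS for p in self.powers):
            raise ValueError(f"powers must come from {FP_POWERS}")

    def column_names(self):
        return [f"{self.variable}_fp{i + 1}" for i in range(len(self.powers))]


def _shift_scale(x):
    """Shift to positivity and scale by a power of ten for stability."""
    x = np.asarray(x, dtype=float)
    lo = np.min(x)
    shift = 0.0 if lo > 0 else -lo + 0.05 * (np.max(x) - lo) + 1e-6
    med = np.median(x + shift)
    scale = 10.0 ** np.floor(np.log10(med)) if med > 0 else 1.0
    return float(shift), float(scale)


def fp_basis(x, spec: FPSpec) -> np.ndarray:
    """Evaluate the FP basis columns for ``x`` (n x degree array)."""
    z = (np.asarray(x, dtype=float) + spec.shift) / spec.scale
    if np.any(z <= 0):
        raise ValueError("shifted/scaled variable must be positive")
    cols = []
    prev = None
    for p in spec.powers:
        col = np.log(z) if p == 0.0 else z ** p
        if prev is not None and p == prev:
            col = col * np.log(z)   # repeated power: x^p * log x
        cols.append(col)
        prev = p
    return np.column_stack(cols)


def _deviance(basis, context):
    """-2 log (partial/quasi) likelihood of a univariable working model."""
    family = context["family"]
    if family == "cox":
        from lifelines import CoxPHFitter
        df = pd.DataFrame(basis, columns=[f"z{i}" for i in range(basis.shape[1])])
        df["T"] = np.asarray(context["time"], dtype=float)
        df["E"] = np.asarray(context["event"], dtype=bool).astype(int)
        cph = CoxPHFitter(penalizer=1e-6)
        cph.fit(df, duration_col="T", event_col="E")
        return -2.0 * cph.log_likelihood_
    if family == "pseudo_cloglog":
        from .models import cloglog_family
        y = np.asarray(context["pseudovalues"], dtype=float)
        X = sm.add_constant(basis)
        res = sm.GLM(y, X, family=cloglog_family()).fit(maxiter=100)
        rss = float(np.sum((y - res.fittedvalues) ** 2))
        # Gaussian profile -2 log likelihood (up to a constant): differences
        # between nested fits are asymptotically chi-squared
        return len(y) * np.log(rss / len(y))
    raise ValueError(f"unknown family {family!r}")


def select_fractional_polynomial(x, context, degree=2, alpha=0.05) -> FPSpec:
    """Choose FP powers for one variable by deviance with a closed test.

    Parameters
    ----------
    x : array-like
        The continuous variable (need not be positive; it is shifted).
    context : dict
        ``{"family": "cox", "time": ..., "event": ...}`` or
        ``{"family": "pseudo_cloglog", "pseudovalues": ...}``.
    degree : int
        Maximum FP degree (1 or 2).
    alpha : float
        Level of the closed test against the linear term.

    The closed test compares the best degree-2 FP against linear on 3
    degrees of freedom; if significant, degree 2 is compared against the
    best degree 1 on 2 df, otherwise the linear spec is returned.
    """
    x = np.asarray(x, dtype=float)
    variable = getattr(x, "name", None) or context.get("variable", "x")
    if np.unique(x).size < 20:
        raise ValueError("need at least 20 distinct values for FP selection")
    shift, scale = _shift_scale(x)

    def dev(powers):
        spec = FPSpec(variable, tuple(powers), shift, scale)
        return _deviance(fp_basis(x, spec), context), spec

    from scipy import stats

    dev_lin, spec_lin = dev((1.0,))
    fp1 = [dev((p,)) for p in FP_POWERS]
    best1 = min(fp1, key=lambda t: t[0])
    if degree < 2:
        if stats.chi2.sf(dev_lin - best1[0], 1) < alpha:
            return best1[1]
        return spec_lin
    fp2 = [dev(c) for c in combinations_with_replacement(FP_POWERS, 2)]
    best2 = min(fp2, key=lambda t: t[0])
    if stats.chi2.sf(dev_lin - best2[0], 3) >= alpha:
        return spec_lin
    if stats.chi2.sf(best1[0] - best2[0], 2) >= alpha:
        return best1[1]
    return best2[1]
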