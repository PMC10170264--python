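"""Jack-knife pseudo-observations of survival functionals at a horizon.

A pseudo-observation for subject i of an estimator ``theta_hat`` is

    theta_i = n * theta_hat - (n - 1) * theta_hat_(-i)

where ``theta_hat_(-i)`` is the estimate recomputed with subject i removed.
Under censoring the pseudo-observations may fall outside [0, 1]; their mean
equals the full-sample estimate exactly (the jack-knife identity).  They can
then serve as a per-subject regression or machine-learning target that
carries the censoring adjustment.

Two targets are supported at horizon ``t*``:

``cif_cause1``
    The Aalen-Johansen cumulative incidence of cause 1, acknowledging the
    competing event (cause 2).
``km_failure``
    1 - S(t*) from the product-limit estimator with cause 1 as the event and
    causes 0 and 2 both treated as censoring (the Cox-model convention).

The leave-one-out estimates are obtained with an O(n) grouped recursion
rather than literal recomputation: removing subject i shrinks every risk set
before its observation time by one and adjusts the counts of its own tie
group, so prefix products of modified factors plus a suffix recursion of
unmodified factors reconstruct all n leave-one-out estimates in one pass.
The literal O(n^2) recomputation is the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nonparametric import _check_times, aalen_johansen, kaplan_meier, risk_table

__all__ = ["PseudovalueSet", "jackknife_pseudovalues"]

_TARGETS = ("cif_cause1", "km_failure")


@dataclass
class PseudovalueSet:
    """Per-subject pseudo-observations of a risk functional at one horizon."""

    horizon: float
    target: str
    values: np.ndarray
    full_sample_estimate: float

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    @property
    def max(self) -> float:
        return float(np.max(self.values))

    def to_frame(self, ids=None) -> pd.DataFrame:
        ids = np.arange(len(self.values)) if ids is None else np.asarray(ids)
        return pd.DataFrame({"id": ids, "pseudovalue": self.values})


def _loo_cif(times, n_at_risk, d1, d2, m):
    """Leave-one-out Aalen-Johansen CIF_1 for every (tie group, status).

    Returns three arrays over groups: the leave-one-out estimate when the
    removed subject of that group was a cause-1 event, a cause-2 event, or
    censored.  ``m`` is the number of leading groups with time <= horizon.
    """
    G = len(times)
    e = d1 + d2
    in_h = np.zeros(G)
    in_h[:m] = 1.0

    nm1 = n_at_risk - 1.0
    safe = np.where(nm1 > 0, nm1, 1.0)
    A = 1.0 - e / n_at_risk                       # unmodified survival factor
    inc = in_h * d1 / n_at_risk                   # unmodified CIF increment
    A_mod = 1.0 - e / safe                        # factor with risk set shrunk
    inc_mod = in_h * d1 / safe

    # prefix products/sums of modified factors (exclusive of the own group)
    P_mod = np.concatenate(([1.0], np.cumprod(A_mod)[:-1]))
    H = np.concatenate(([0.0], np.cumsum(P_mod * inc_mod)[:-1]))

    # suffix recursion of unmodified factors: T[g] = inc[g+1] + A[g+1]*T[g+1]
    T = np.zeros(G)
    for g in range(G - 2, -1, -1):
        T[g] = inc[g + 1] + A[g + 1] * T[g + 1]

    out = {}
    for status in (1, 2, 0):
        d1_own = d1 - (1 if status == 1 else 0)
        e_own = e - (1 if status in (1, 2) else 0)
        f_own = np.where(nm1 > 0, 1.0 - e_own / safe, 1.0)
        inc_own = np.where(nm1 > 0, in_h * d1_own / safe, 0.0)
        out[status] = H + P_mod * (inc_own + f_own * T)
    return out


def _loo_km_failure(times, n_at_risk, d1, m):
    """Leave-one-out KM failure probability for every (tie group, status)."""
    G = len(times)
    nm1 = n_at_risk - 1.0
    safe = np.where(nm1 > 0, nm1, 1.0)
    B = 1.0 - d1 / n_at_risk
    B_mod = 1.0 - d1 / safe

    P_mod = np.concatenate(([1.0], np.cumprod(B_mod)[:-1]))
    # suffix product of unmodified factors restricted to groups <= horizon
    Q = np.ones(G + 1)
    for g in range(G - 1, -1, -1):
        Q[g] = (B[g] if g < m else 1.0) * Q[g + 1]
    prod_all_mod = float(np.prod(B_mod[:m])) if m > 0 else 1.0

    out = {}
    for status in (1, 2, 0):
        d1_own = d1 - (1 if status == 1 else 0)
        f_own = np.where(nm1 > 0, 1.0 - d1_own / safe, 1.0)
        est = np.empty(G)
        inside = np.arange(G) < m
        est[inside] = 1.0 - P_mod[inside] * f_own[inside] * Q[1:][inside]
        # subject observed after the horizon: only earlier risk sets shrink
        est[~inside] = 1.0 - prod_all_mod
        out[status] = est
    return out


def jackknife_pseudovalues(time, cause, tstar, target="cif_cause1") -> PseudovalueSet:
    """Compute jack-knife pseudo-observations at horizon ``tstar``.

    Parameters
    ----------
    time, cause : array-like
        Follow-up times (> 0) and cause codes {0 censored, 1 event of
        interest, 2 competing event}.
    tstar : float
        The evaluation horizon (> 0), e.g. 10 years.
    target : str
        ``cif_cause1`` (Aalen-Johansen, competing-risks scale) or
        ``km_failure`` (cause 2 treated as censoring).
    """
    time = _check_times(time)
    cause = np.asarray(cause, dtype=int)
    n = len(time)
    if n < 2:
        raise ValueError("pseudo-observations require at least two subjects")
    if tstar <= 0:
        raise ValueError("horizon must be positive")
    if target not in _TARGETS:
        raise ValueError(f"unknown target {target!r}; choose from {_TARGETS}")

    times, n_at_risk, d1, d2, _ = risk_table(time, cause)
    m = int(np.searchsorted(times, tstar, side="right"))

    if target == "cif_cause1":
        full = float(aalen_johansen(time, cause, 1)(tstar))
        loo = _loo_cif(times, n_at_risk.astype(float), d1.astype(float),
                       d2.astype(float), m)
    else:
        full = 1.0 - float(kaplan_meier(time, cause == 1)(tstar))
        loo = _loo_km_failure(times, n_at_risk.astype(float),
                              d1.astype(float), m)

    group_idx = np.searchsorted(times, time)
    theta = np.empty(n)
    for status in (0, 1, 2):
        mask = cause == status
        theta[mask] = n * full - (n - 1) * loo[status][group_idx[mask]]
    return PseudovalueSet(horizon=float(tstar), target=target, values=theta,
                          full_sample_estimate=full)
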