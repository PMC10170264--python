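"""Nonparametric estimators for right-censored competing-risks data.

Implements the product-limit (Kaplan-Meier) estimator, the Aalen-Johansen
cumulative incidence function, the Kaplan-Meier estimate of the censoring
distribution, and the Nelson-Aalen cumulative hazard.  All estimators share
one grouped risk-set decomposition so that the jack-knife pseudo-observation
recursions in :mod:`pseudorisk.pseudo` can reuse the exact same tie
convention: subjects with tied times are grouped, events and censorings at a
tied time are both counted as at risk at that time, and censorings leave the
risk set after the events are processed.

Step estimates are right-continuous: a query between jumps returns the value
at the preceding jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepEstimate",
    "risk_table",
    "kaplan_meier",
    "aalen_johansen",
    "aalen_johansen_cif",
    "censoring_survival",
    "nelson_aalen",
]


@dataclass
class StepEstimate:
    """A piecewise-constant, right-continuous estimate over time.

    Parameters
    ----------
    times : ndarray
        Sorted unique jump times (years).
    values : ndarray
        Value of the estimate immediately after each jump time.
    kind : str
        One of ``survival``, ``cif``, ``censoring_survival``, ``cumhaz``.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    baseline: float = field(default=None)  # value before the first jump

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.baseline is None:
            self.baseline = 0.0 if self.kind in ("cif", "cumhaz") else 1.0

    def __call__(self, t):
        """Evaluate the step function at time(s) ``t`` (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.baseline)
        return out if out.ndim else float(out)

    def left_limit(self, t):
        """Evaluate at ``t-`` (the value just before a jump at ``t``)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.baseline)
        return out if out.ndim else float(out)


def _check_times(time):
    time = np.asarray(time, dtype=float)
    if time.size == 0:
        raise ValueError("empty input: at least one observation is required")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("follow-up times must be positive and finite")
    return time


def risk_table(time, cause):
    """Group observations by unique time and tabulate the risk sets.

    Returns
    -------
    tuple of ndarrays
        ``(times, n_at_risk, d_cause1, d_cause2, n_censored)`` where
        ``n_at_risk`` counts every subject with observed time >= the group
        time (the tie convention above).
    """
    time = _check_times(time)
    cause = np.asarray(cause, dtype=int)
    if cause.shape != time.shape:
        raise ValueError("time and cause must have equal length")
    if not np.isin(cause, (0, 1, 2)).all():
        raise ValueError("cause codes must be 0 (censored), 1 or 2")
    order = np.argsort(time, kind="mergesort")
    t_sorted = time[order]
    c_sorted = cause[order]
    times, start = np.unique(t_sorted, return_index=True)
    G = len(times)
    bounds = np.append(start, len(t_sorted))
    d1 = np.zeros(G, dtype=int)
    d2 = np.zeros(G, dtype=int)
    cz = np.zeros(G, dtype=int)
    for g in range(G):
        cg = c_sorted[bounds[g]:bounds[g + 1]]
        d1[g] = int((cg == 1).sum())
        d2[g] = int((cg == 2).sum())
        cz[g] = int((cg == 0).sum())
    removed = d1 + d2 + cz
    n_at_risk = len(time) - np.concatenate(([0], np.cumsum(removed)[:-1]))
    return times, n_at_risk, d1, d2, cz


def kaplan_meier(time, event) -> StepEstimate:
    """Product-limit survival estimate treating ``event`` as the endpoint.

    ``event`` is a boolean/0-1 indicator; non-events are censored.
    Evaluation beyond the last observed time carries the last value forward.
    """
    time = _check_times(time)
    event = np.asarray(event).astype(bool)
    cause = np.where(event, 1, 0)
    times, n, d1, _, _ = risk_table(time, cause)
    factors = 1.0 - d1 / n
    surv = np.cumprod(factors)
    return StepEstimate(times, surv, kind="survival")


def censoring_survival(time, cause) -> StepEstimate:
    """Kaplan-Meier estimate of the censoring distribution G(t).

    Cause 0 (censoring) is treated as the event; causes 1 and 2 are
    censored.  This is the ingredient of inverse-probability-of-censoring
    weights.
    """
    time = _check_times(time)
    cause = np.asarray(cause, dtype=int)
    est = kaplan_meier(time, cause == 0)
    est.kind = "censoring_survival"
    return est


def nelson_aalen(time, event) -> StepEstimate:
    """Nelson-Aalen cumulative hazard H(t) = sum d_j / n_j.

    The per-subject auxiliary value used in imputation models is
    ``nelson_aalen(time, event)(time_i)`` for each subject i.
    """
    time = _check_times(time)
    event = np.asarray(event).astype(bool)
    times, n, d1, _, _ = risk_table(time, np.where(event, 1, 0))
    cumhaz = np.cumsum(d1 / n)
    return StepEstimate(times, cumhaz, kind="cumhaz")


def aalen_johansen(time, cause, cause_of_interest=1) -> StepEstimate:
    """Aalen-Johansen cumulative incidence function for one cause.

    CIF_k(t) = sum_{t_j <= t} S(t_j-) d_kj / n_j with S the all-cause
    product-limit survival.  Causes absent from the data give a CIF that is
    identically zero.
    """
    time = _check_times(time)
    times, n, d1, d2, _ = risk_table(time, cause)
    dk = d1 if cause_of_interest == 1 else d2
    e = d1 + d2
    surv = np.cumprod(1.0 - e / n)
    surv_minus = np.concatenate(([1.0], surv[:-1]))
    cif = np.cumsum(surv_minus * dk / n)
    return StepEstimate(times, cif, kind="cif")


def aalen_johansen_cif(time, cause, tstar, cause_of_interest=1) -> float:
    """The Aalen-Johansen CIF for ``cause_of_interest`` evaluated at ``tstar``."""
    if tstar <= 0:
        raise ValueError("evaluation time must be positive")
    return float(aalen_johansen(time, cause, cause_of_interest)(tstar))
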