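"""Hyperparameter search for the pseudo-observation machine learners.

The tuner minimises k-fold cross-validated root mean squared error between
observed pseudo-observations and model predictions.  The default strategy
is seeded random search over the declared ranges; the default configuration
is always evaluated first, so the returned configuration can never be worse
than the default in CV-RMSE, and enlarging the budget with the same seed
only extends the candidate sequence (monotone improvement).
"""

from __future__ import annotations

import numpy as np

from .models import PseudoMLPRisk, PseudoXGBRisk

__all__ = ["GBT_RANGES", "FFNN_RANGES", "tune_hyperparameters", "make_learner"]

# search ranges for the tree booster and the feed-forward net
GBT_RANGES = {
    "max_depth": ("int", 1, 6),
    "eta": ("log", 1e-4, 0.1),
    "subsample": ("float", 0.1, 0.5),
    "n_rounds": ("int", 1, 500),
    "alpha": ("float", 0.0, 20.0),
    "gamma": ("float", 0.0, 20.0),
    "reg_lambda": ("float", 0.0, 20.0),
    "colsample_bytree": ("float", 0.1, 0.8),
    "colsample_bylevel": ("float", 0.1, 0.8),
}
FFNN_RANGES = {
    "n_hidden_layers": ("int", 1, 5),
    "n_units": ("int", 26, 50),
    "epochs": ("int", 1, 50),
    "learning_rate": ("log", 1e-3, 0.1),
}


def make_learner(kind, config=None, seed=0):
    config = dict(config or {})
    if kind == "gbt":
        return PseudoXGBRisk(seed=seed, **config)
    if kind == "ffnn":
        return PseudoMLPRisk(seed=seed, **config)
    raise ValueError(f"unknown learner kind {kind!r}")


def _sample(ranges, rng):
    config = {}
    for name, (typ, lo, hi) in ranges.items():
        if typ == "int":
            config[name] = int(rng.integers(lo, hi + 1))
        elif typ == "log":
            config[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            config[name] = float(rng.uniform(lo, hi))
    return config


def _check_in_ranges(config, ranges):
    for name, value in config.items():
        if name not in ranges:
            continue
        _, lo, hi = ranges[name]
        if not (lo <= value <= hi):
            raise ValueError(f"{name}={value} outside declared range [{lo}, {hi}]")


def cv_rmse(kind, config, X, y, k_folds=5, seed=0):
    """k-fold cross-validated RMSE of one configuration."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, k_folds)
    sq, cnt = 0.0, 0
    for i in range(k_folds):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(k_folds) if j != i])
        model = make_learner(kind, config, seed=seed + i)
        model.fit(X[train], y[train])
        pred = model.predict_raw(X[test])
        sq += float(np.sum((pred - y[test]) ** 2))
        cnt += len(test)
    return np.sqrt(sq / cnt)


def tune_hyperparameters(kind, X, y, k_folds=5, budget=30, seed=0,
                         ranges=None, default_config=None):
    """Random-search tuning of a pseudo-observation learner.

    Returns ``(best_config, best_cv_rmse, history)``; the first candidate
    is the learner's default configuration, so the result is never worse
    than the default.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    if budget < 1:
        raise ValueError("budget must be at least 1")
    ranges = ranges or (GBT_RANGES if kind == "gbt" else FFNN_RANGES)
    if default_config is None:
        proto = make_learner(kind)
        default_config = {k: getattr(proto, k) for k in ranges}
    rng = np.random.default_rng(seed)
    candidates = [default_config] + [_sample(ranges, rng)
                                     for _ in range(budget - 1)]
    history = []
    best_config, best_rmse = None, np.inf
    for config in candidates:
        _check_in_ranges(config, ranges)
        rmse = cv_rmse(kind, config, X, y, k_folds=k_folds, seed=seed)
        history.append({"config": config, "cv_rmse": rmse})
        if rmse < best_rmse:
            best_config, best_rmse = config, rmse
    return best_config, best_rmse, history
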