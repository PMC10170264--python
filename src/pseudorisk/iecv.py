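"""Internal-external cross-validation of the four modelling strategies.

The cohort is split by region and calendar period: models are developed on
period-1 data (with follow-up truncated at the period boundary so the two
periods form wholly distinct datasets), the held-out region's period-2 data
form the test set, and region-level discrimination/calibration metrics are
pooled across imputations by Rubin's rules and across regions by
Hartung-Knapp-Sidik-Jonkman random-effects meta-analysis.

Two split modes are provided because the geographic component can be read
two ways: ``geo_temporal`` (default) excludes the held-out region from
training entirely, measuring joint geographic and temporal transfer;
``temporal`` trains on all regions' period-1 data.

Machine-learning hyperparameters are tuned inside each training set by
k-fold cross-validation (nested cross-validation); pseudo-observations are
computed separately within each training and each test stratum.  An audit
of subject ids per split verifies that no test-period observation enters
any training computation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import truncate_followup
from .design import DEFAULT_PREDICTORS, build_design
from .fp import select_fractional_polynomial
from .impute import mice_impute
from .meta import hksj_random_effects, meta_regression, pool_metric_over_imputations
from .metrics import (calibration_slope_citl, decision_curve, harrells_c,
                      ipcw_c_index, subgroup_metrics)
from .models import (fit_pooled_cloglog, fit_pooled_cox, select_predictors)
from .pseudo import jackknife_pseudovalues
from .tuning import make_learner, tune_hyperparameters

__all__ = ["IECVConfig", "IECVResult", "run_iecv", "fit_final_models",
           "make_report", "events_per_parameter"]

ALL_MODELS = ("cox", "crr", "gbt", "ffnn")


@dataclass
class IECVConfig:
    models: tuple = ALL_MODELS
    horizon: float = 10.0
    period_boundary: float = 10.0
    m_imputations: int = 5
    n_cycles: int = 5
    tuner_budget: int = 15
    k_folds: int = 5
    thresholds: tuple = tuple(np.round(np.arange(0.01, 0.501, 0.01), 4))
    seed: int = 0
    mode: str = "geo_temporal"          # or "temporal"
    fp_variables: tuple = ("age", "bmi")
    predictors: tuple = tuple(DEFAULT_PREDICTORS)
    select: bool = True
    penalizer: float = 1e-4

    def __post_init__(self):
        if not self.models:
            raise ValueError("model list must be non-empty")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.mode not in ("geo_temporal", "temporal"):
            raise ValueError("mode must be geo_temporal or temporal")


@dataclass
class IECVResult:
    region_metrics: pd.DataFrame        # per (model, region, imputation)
    pooled_region_metrics: pd.DataFrame  # per (model, region), Rubin-pooled
    meta_results: dict                  # (model, metric) -> MetaResult
    meta_regression: dict               # (model, metric) -> MetaRegResult
    predictions: pd.DataFrame           # pooled individual test predictions
    decision_curves: dict               # (model, competing) -> DecisionCurve
    subgroup_tables: dict               # (model, grouping) -> DataFrame
    audit: dict
    config: IECVConfig


def _hash_ids(ids) -> str:
    payload = ",".join(str(int(i)) for i in sorted(ids))
    return hashlib.sha256(payload.encode()).hexdigest()


def _seeds(master, n):
    ss = np.random.SeedSequence(master)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _fp_specs_for(datasets, variables, family, horizon, pseudovalues=None):
    """FP term selection on the first completed training dataset."""
    specs = {}
    df = datasets[0]
    for var in variables:
        x = df[var].to_numpy()
        if family == "cox":
            ctx = {"family": "cox", "time": df["time"].to_numpy(),
                   "event": (df["cause"] == 1).to_numpy(),
                   "variable": var}
        else:
            ctx = {"family": "pseudo_cloglog", "pseudovalues": pseudovalues,
                   "variable": var}
        try:
            specs[var] = select_fractional_polynomial(x, ctx)
        except ValueError:
            continue
    return specs


def _fit_regression(kind, datasets, pseudovalues, config):
    """FP selection -> full fit -> rule-based selection -> refit."""
    fp = _fp_specs_for(datasets, config.fp_variables,
                       "cox" if kind == "cox" else "pseudo_cloglog",
                       config.horizon, pseudovalues)
    predictors = list(config.predictors)
    if kind == "cox":
        full, _ = fit_pooled_cox(datasets, predictors, fp, config.horizon,
                                 penalizer=config.penalizer)
    else:
        full, _ = fit_pooled_cloglog(datasets, pseudovalues, predictors, fp,
                                     config.horizon)
    if config.select:
        table = full.coef_table[full.coef_table["variable"] != "const"]
        selected = select_predictors(table)
        if not selected:
            selected = predictors   # degenerate: keep the full model
    else:
        selected = predictors
    fp_sel = {v: s for v, s in fp.items() if v in selected}
    if kind == "cox":
        model, _ = fit_pooled_cox(datasets, selected, fp_sel, config.horizon,
                                  penalizer=config.penalizer)
    else:
        model, _ = fit_pooled_cloglog(datasets, pseudovalues, selected,
                                      fp_sel, config.horizon)
    return model, selected, fp_sel


def _fit_ml(kind, datasets, pseudovalues, predictors, fp_specs, config, seed):
    """Tune on the stacked training imputations, then fit on the stack."""
    X_parts = [build_design(df, predictors, fp_specs)[0] for df in datasets]
    X = pd.concat(X_parts, ignore_index=True)
    y = np.concatenate([pseudovalues] * len(datasets))
    budget = config.tuner_budget
    if budget > 0:
        best, _, _ = tune_hyperparameters(kind, X, y, k_folds=config.k_folds,
                                          budget=budget, seed=seed)
    else:
        best = None
    learner = make_learner(kind, best, seed=seed)
    learner.fit(X, y)
    return learner, best


def events_per_parameter(events, n_parameters) -> float:
    """Events per candidate predictor parameter (sample-size arithmetic)."""
    if n_parameters <= 0:
        raise ValueError("number of parameters must be positive")
    return events / n_parameters


def run_iecv(cohort: pd.DataFrame, config: IECVConfig) -> IECVResult:
    """Run the full internal-external cross-validation loop."""
    p1, p2 = truncate_followup(cohort, config.period_boundary, config.horizon)
    regions = sorted(cohort["region"].unique())
    usable = [r for r in regions
              if ((p1["region"] == r) & (p1["cause"] == 1)).sum() > 0
              and ((p2["region"] == r) & (p2["cause"] == 1)).sum() > 0]
    if len(usable) < 3:
        raise ValueError("need at least three regions with events in both periods")
    dropped = sorted(set(regions) - set(usable))
    if dropped:
        warnings.warn(f"regions without events in both periods excluded: "
                      f"{dropped}", stacklevel=2)

    seeds = _seeds(config.seed, 4 + len(usable))
    stack1 = mice_impute(p1, m=config.m_imputations, n_cycles=config.n_cycles,
                         seed=seeds[0], horizon=config.horizon)
    stack2 = mice_impute(p2, m=config.m_imputations, n_cycles=config.n_cycles,
                         seed=seeds[1], horizon=config.horizon)

    rows = []
    pred_rows = []
    audit = {}
    for ridx, r in enumerate(usable):
        if config.mode == "geo_temporal":
            train_sets = [d[d["region"] != r].reset_index(drop=True)
                          for d in stack1]
        else:
            train_sets = [d.reset_index(drop=True) for d in stack1]
        test_sets = [d[d["region"] == r].reset_index(drop=True)
                     for d in stack2]
        train_ids = set(train_sets[0]["id"])
        test_ids = set(test_sets[0]["id"])
        audit[str(r)] = {
            "train_hash": _hash_ids(train_ids),
            "test_hash": _hash_ids(test_ids),
            "n_train": len(train_ids), "n_test": len(test_ids),
            "overlap": len(train_ids & test_ids),
        }

        t_tr = train_sets[0]["time"].to_numpy()
        c_tr = train_sets[0]["cause"].to_numpy()
        pv_train_cif = jackknife_pseudovalues(t_tr, c_tr, config.horizon,
                                              "cif_cause1").values
        t_te = test_sets[0]["time"].to_numpy()
        c_te = test_sets[0]["cause"].to_numpy()
        pv_test_cif = jackknife_pseudovalues(t_te, c_te, config.horizon,
                                             "cif_cause1").values
        pv_test_km = jackknife_pseudovalues(t_te, c_te, config.horizon,
                                            "km_failure").values

        fold_models = {}
        crr_sel, crr_fp = list(config.predictors), {}
        for kind in ("cox", "crr"):
            if kind not in config.models and not (
                    kind == "crr" and {"gbt", "ffnn"} & set(config.models)):
                continue
            model, sel, fps = _fit_regression(
                kind, train_sets, pv_train_cif if kind == "crr" else None,
                config)
            fold_models[kind] = model
            if kind == "crr":
                crr_sel, crr_fp = sel, fps
        for kind in ("gbt", "ffnn"):
            if kind not in config.models:
                continue
            learner, _ = _fit_ml(kind, train_sets, pv_train_cif, crr_sel,
                                 crr_fp, config, seeds[4 + ridx])
            fold_models[kind] = learner

        for kind in config.models:
            model = fold_models[kind]
            per_imp_preds = []
            for j, test_df in enumerate(test_sets, start=1):
                if kind in ("cox", "crr"):
                    pred = model.predict(test_df)
                else:
                    X_te = build_design(test_df, crr_sel, crr_fp)[0]
                    pred = model.predict(X_te)
                per_imp_preds.append(pred)
                if kind == "cox":
                    cm = harrells_c(t_te, c_te == 1, pred, config.horizon,
                                    region=r, imputation=j)
                    pv = pv_test_km
                else:
                    cm = ipcw_c_index(t_te, c_te, pred, config.horizon,
                                      region=r, imputation=j)
                    pv = pv_test_cif
                try:
                    slope, citl = calibration_slope_citl(pv, pred, region=r,
                                                         imputation=j)
                    srow = (slope.value, slope.se, citl.value, citl.se)
                except ValueError:
                    srow = (np.nan, np.nan, np.nan, np.nan)
                rows.append({"model": kind, "region": r, "imputation": j,
                             "c_index": cm.value, "c_se": cm.se,
                             "slope": srow[0], "slope_se": srow[1],
                             "citl": srow[2], "citl_se": srow[3]})
            mean_pred = np.mean(per_imp_preds, axis=0)
            pred_rows.append(pd.DataFrame({
                "model": kind, "region": r, "id": test_sets[0]["id"],
                "time": t_te, "cause": c_te,
                "stage": test_sets[0]["stage"],
                "age": test_sets[0]["age"],
                "prediction": mean_pred,
                "pv_cif": pv_test_cif, "pv_km": pv_test_km}))

    region_metrics = pd.DataFrame(rows)
    predictions = pd.concat(pred_rows, ignore_index=True)

    # Rubin pooling per (model, region), then HKSJ meta-analysis per model
    pooled_rows = []
    meta_results = {}
    for kind in config.models:
        sub = region_metrics[region_metrics["model"] == kind]
        from .metrics import ClusterMetric
        for metric, se_col in (("c_index", "c_se"), ("slope", "slope_se"),
                               ("citl", "citl_se")):
            cms = [ClusterMetric(metric, v, s, region=rr, imputation=jj)
                   for v, s, rr, jj in zip(sub[metric], sub[se_col],
                                           sub["region"], sub["imputation"])
                   if np.isfinite(v) and np.isfinite(s) and s > 0]
            if not cms:
                continue
            pooled = (pool_metric_over_imputations(cms)
                      if config.m_imputations > 1 else cms)
            for cm in pooled:
                pooled_rows.append({"model": kind, "metric": metric,
                                    "region": cm.region, "value": cm.value,
                                    "se": cm.se})
            est = [cm.value for cm in pooled]
            ses = [cm.se for cm in pooled]
            if len(est) >= 2:
                meta_results[(kind, metric)] = hksj_random_effects(est, ses)
    pooled_region_metrics = pd.DataFrame(pooled_rows)

    # meta-regression on region-level covariates from period-2 data
    covs = p2.groupby("region").agg(age_sd=("age", "std"),
                                    bmi_mean=("bmi", "mean"),
                                    deprivation_mean=("deprivation", "mean"))
    metareg = {}
    for (kind, metric), _ in meta_results.items():
        sub = pooled_region_metrics[
            (pooled_region_metrics["model"] == kind)
            & (pooled_region_metrics["metric"] == metric)]
        X = covs.loc[sub["region"]].reset_index(drop=True)
        if len(sub) > X.shape[1] + 2:
            try:
                metareg[(kind, metric)] = meta_regression(
                    sub["value"].to_numpy(), sub["se"].to_numpy(), X)
            except ValueError:
                pass

    # decision curves and subgroup metrics on pooled individual predictions
    curves = {}
    subgroups = {}
    for kind in config.models:
        sub = predictions[predictions["model"] == kind]
        for competing in (True, False):
            curves[(kind, competing)] = decision_curve(
                sub["time"].to_numpy(), sub["cause"].to_numpy(),
                sub["prediction"].to_numpy(), config.horizon,
                np.asarray(config.thresholds), competing=competing)
        frame = sub.reset_index(drop=True).copy()
        frame["age_band"] = (frame["age"] // 10 * 10).astype(int)
        for grouping in ("stage", "age_band"):
            subgroups[(kind, grouping)] = subgroup_metrics(
                frame, frame["prediction"].to_numpy(), grouping,
                horizon=config.horizon,
                target="km_failure" if kind == "cox" else "cif_cause1")

    audit["total_overlap"] = int(sum(v["overlap"] for v in audit.values()
                                     if isinstance(v, dict)))
    return IECVResult(region_metrics, pooled_region_metrics, meta_results,
                      metareg, predictions, curves, subgroups, audit, config)


def fit_final_models(cohort: pd.DataFrame, config: IECVConfig) -> dict:
    """Fit all requested strategies to the entire cohort.

    Follow-up is truncated to the horizon but not at the period boundary
    (the boundary only matters for the cross-validation splits).  Returns a
    dict with the fitted models, the selected predictors and the
    pseudo-observation sets; the regression models are JSON-serialisable.
    """
    seeds = _seeds(config.seed, 3)
    df = cohort.copy()
    over = df["time"] > config.horizon
    df.loc[over, "time"] = config.horizon
    df.loc[over, "cause"] = 0
    stack = mice_impute(df, m=config.m_imputations, n_cycles=config.n_cycles,
                        seed=seeds[0], horizon=config.horizon)
    t = df["time"].to_numpy()
    c = df["cause"].to_numpy()
    pv_cif = jackknife_pseudovalues(t, c, config.horizon, "cif_cause1").values
    out = {"pseudovalues_cif": pv_cif}
    crr_sel, crr_fp = list(config.predictors), {}
    need_crr = ("crr" in config.models) or ({"gbt", "ffnn"} & set(config.models))
    if "cox" in config.models:
        model, sel, fps = _fit_regression("cox", list(stack), None, config)
        out["cox"] = model
        out["cox_predictors"] = sel
    if need_crr:
        model, sel, fps = _fit_regression("crr", list(stack), pv_cif, config)
        out["crr"] = model
        out["crr_predictors"] = sel
        crr_sel, crr_fp = sel, fps
    for kind in ("gbt", "ffnn"):
        if kind in config.models:
            learner, best = _fit_ml(kind, list(stack), pv_cif, crr_sel,
                                    crr_fp, config, seeds[1])
            out[kind] = learner
            out[f"{kind}_config"] = best
            out[f"{kind}_predictors"] = crr_sel
            out[f"{kind}_fp_specs"] = crr_fp
    return out


def make_report(result: IECVResult, outdir):
    """Write metric tables, forest-plot inputs and figures for one run."""
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.region_metrics.to_csv(outdir / "region_metrics.tsv", sep="\t",
                                 index=False)
    result.pooled_region_metrics.to_csv(outdir / "region_metrics_pooled.tsv",
                                        sep="\t", index=False)
    pooled = [{"model": k[0], "metric": k[1], **m.to_dict()}
              for k, m in result.meta_results.items()]
    pd.DataFrame(pooled).to_csv(outdir / "pooled_metrics.tsv", sep="\t",
                                index=False)
    forest = result.pooled_region_metrics.copy()
    forest["ci_low"] = forest["value"] - 1.959964 * forest["se"]
    forest["ci_high"] = forest["value"] + 1.959964 * forest["se"]
    forest.to_csv(outdir / "forest_inputs.tsv", sep="\t", index=False)
    if result.meta_regression:
        mr = [{"model": k[0], "metric": k[1], "tau2": v.tau2,
               "tau2_null": v.tau2_null, "r2": v.r2,
               "residual_i2": v.residual_i2}
              for k, v in result.meta_regression.items()]
        pd.DataFrame(mr).to_csv(outdir / "meta_regression.tsv", sep="\t",
                                index=False)
    for (kind, grouping), table in result.subgroup_tables.items():
        table.to_csv(outdir / f"subgroup_{kind}_{grouping}.tsv", sep="\t",
                     index=False)
    curve_rows = []
    for (kind, competing), dc in result.decision_curves.items():
        frame = dc.to_frame()
        frame.insert(0, "model", kind)
        frame.insert(1, "competing_risks", competing)
        curve_rows.append(frame)
    pd.concat(curve_rows, ignore_index=True).to_csv(
        outdir / "decision_curves.tsv", sep="\t", index=False)
    with open(outdir / "audit.json", "w") as fh:
        json.dump(result.audit, fh, indent=1, sort_keys=True)
    with open(outdir / "run_config.json", "w") as fh:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(result.config).items()}
        json.dump(cfg, fh, indent=1, sort_keys=True)

    # calibration figure: smoothed observed vs predicted, per model
    from .metrics import smoothed_calibration_curve
    models = list(result.config.models)
    fig, axes = plt.subplots(2, len(models), figsize=(4 * len(models), 7),
                             squeeze=False)
    for ax_idx, kind in enumerate(models):
        sub = result.predictions[result.predictions["model"] == kind]
        pv = sub["pv_km"] if kind == "cox" else sub["pv_cif"]
        try:
            curve = smoothed_calibration_curve(sub["prediction"].to_numpy(),
                                               pv.to_numpy())
            axes[0][ax_idx].plot(curve["predicted"], curve["observed"])
            axes[0][ax_idx].plot([0, 1], [0, 1], "k--", lw=0.8)
        except ValueError:
            pass
        axes[0][ax_idx].set_title(kind)
        axes[0][ax_idx].set_xlabel("predicted risk")
        axes[0][ax_idx].set_ylabel("observed (pseudo-obs smooth)")
        axes[1][ax_idx].hist(sub["prediction"], bins=30)
        axes[1][ax_idx].set_xlabel("predicted risk")
    fig.tight_layout()
    fig.savefig(outdir / "calibration.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for (kind, competing), dc in result.decision_curves.items():
        if competing:
            ax.plot(dc.thresholds, dc.net_benefit, label=kind)
    any_dc = next(iter(result.decision_curves.values()))
    ax.plot(any_dc.thresholds, any_dc.treat_all, "k:", label="treat all")
    ax.axhline(0.0, color="grey", lw=0.8, label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "decision_curves.png", dpi=120)
    plt.close(fig)
    return outdir
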