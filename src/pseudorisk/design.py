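"""Design-matrix construction shared by all four modelling strategies.

Categorical variables are dummy-coded against a fixed reference level (the
first of the declared level set, so encodings are stable across subsamples
and imputations); continuous variables enter linearly or through a
fractional-polynomial basis; binary flags enter as 0/1 columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_LEVELS
from .fp import FPSpec, fp_basis

__all__ = ["VARIABLE_TYPES", "DEFAULT_PREDICTORS", "build_design"]

VARIABLE_TYPES = {
    "age": "continuous", "bmi": "continuous", "deprivation": "continuous",
    "stage": "categorical", "grade": "categorical", "route": "categorical",
    "smoking": "categorical",
    "er": "binary", "pr": "binary", "her2": "binary",
    "comorbidity": "binary", "hrt": "binary",
}

DEFAULT_PREDICTORS = ["age", "bmi", "deprivation", "stage", "grade", "er",
                      "pr", "her2", "route", "smoking", "comorbidity", "hrt"]


def build_design(df: pd.DataFrame, predictors=None, fp_specs=None):
    """Build the numeric design matrix and its term metadata.

    Returns
    -------
    (DataFrame, DataFrame)
        The design matrix, and a metadata table with one row per term
        (columns: ``term``, ``variable``, ``type``).
    """
    predictors = DEFAULT_PREDICTORS if predictors is None else list(predictors)
    fp_specs = fp_specs or {}
    cols, meta = {}, []
    for var in predictors:
        vtype = VARIABLE_TYPES.get(var, "binary")
        if var not in df.columns:
            raise KeyError(f"predictor {var!r} missing from data")
        if df[var].isna().any():
            raise ValueError(f"predictor {var!r} contains missing values; "
                             "impute before building the design")
        if vtype == "continuous":
            if var in fp_specs:
                spec: FPSpec = fp_specs[var]
                basis = fp_basis(df[var].to_numpy(), spec)
                for j, name in enumerate(spec.column_names()):
                    cols[name] = basis[:, j]
                    meta.append((name, var, "continuous"))
            else:
                cols[var] = df[var].to_numpy(dtype=float)
                meta.append((var, var, "continuous"))
        elif vtype == "categorical":
            levels = CATEGORICAL_LEVELS.get(var)
            if levels is None:
                levels = sorted(df[var].dropna().unique())
            vals = df[var]
            if not isinstance(levels[0], str):
                vals = vals.astype(float).round().astype(int)
            for lev in levels[1:]:
                name = f"{var}_{lev}"
                cols[name] = (vals == lev).astype(float).to_numpy()
                meta.append((name, var, "categorical"))
        else:
            cols[var] = df[var].astype(float).to_numpy()
            meta.append((var, var, "binary"))
    design = pd.DataFrame(cols, index=df.index)
    meta = pd.DataFrame(meta, columns=["term", "variable", "type"])
    return design, meta
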