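"""Synthetic cohorts with the competing-risks, multi-region, two-period
structure of a linked cancer-registry study.

The generator produces one row per subject: follow-up time in years, a cause
code (0 censored, 1 event of interest, 2 competing event), a geographic
region, a calendar period, mixed continuous/categorical covariates, and an
analytic ground-truth event probability at the horizon for recovery tests.

Event mechanism
---------------
Cause-1 events follow a Fine-Gray mixture so the subdistribution scale is
under direct control: the probability of ever failing from cause 1 is

    P(cause = 1 | X) = 1 - (1 - p_base) ** exp(eta_1)

with eta_1 = X beta_sub + region intercept (+ log period-2 multiplier), and
conditional cause-1 times drawn by inverse transform of

    F_1(t | X) = 1 - (1 - p_base * (1 - exp(-rho * t))) ** exp(eta_1).

On the complementary-log-log scale this is exactly linear in X, so a cloglog
GLM on CIF pseudo-observations targets beta_sub directly.  Cause-2 times are
exponential with a log-linear hazard in X; censoring is exponential and
covariate-independent, plus administrative censoring at the horizon.

All generator parameters are artifact choices: the real study's
covariate-outcome process is unknown, so the defaults only emulate its
qualitative structure (10 regions, two periods with a lower rate in period
2, 10-25%% ten-year cumulative incidence, missing-at-random gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "CATEGORICAL_LEVELS",
    "generate_cohort",
    "simulate_event_times",
    "inject_missingness",
    "truncate_followup",
    "write_cohort",
    "read_cohort",
]

# fixed level sets so dummy coding is stable across subsamples
CATEGORICAL_LEVELS = {
    "stage": [1, 2, 3, 4],
    "grade": [1, 2, 3],
    "route": ["screen", "gp_referral", "emergency", "other"],
    "smoking": [0, 1, 2],  # never / former / current
}

#: covariates that the default missingness configuration may mask
MASKABLE = ("bmi", "stage", "grade", "er", "pr", "her2", "smoking", "deprivation")


def _default_beta_sub():
    # effects on the cloglog/subdistribution scale of standardised covariates
    return {
        "age_std": 0.40,
        "age_std_sq": 0.15,       # non-linear age effect
        "bmi_std": 0.10,
        "deprivation_std": 0.08,
        "stage_num": 0.55,        # per stage above I
        "grade_num": 0.30,        # per grade above 1
        "er": -0.45,
        "her2": 0.20,
        "screen_detected": -0.30,
        "smoking_num": 0.15,
    }


def _default_beta_competing():
    return {
        "age_std": 1.00,
        "age_std_sq": 0.30,
        "deprivation_std": 0.10,
        "comorbidity": 0.60,
        "smoking_num": 0.25,
    }


def _default_mar_config():
    # logit of the masking probability; conditions only on always-observed
    # variables (age, period, comorbidity).  Period 1 has more missingness,
    # mirroring the sparser early registry coverage.
    return {
        "bmi": {"intercept": -1.8, "period1": 1.0, "age_std": 0.2},
        "stage": {"intercept": -1.2, "period1": 1.4},
        "grade": {"intercept": -1.6, "period1": 0.7},
        "er": {"intercept": -0.9, "period1": 1.6},
        "pr": {"intercept": -0.8, "period1": 1.6},
        "her2": {"intercept": -0.9, "period1": 1.7},
        "smoking": {"intercept": -2.6, "period1": 0.8},
        "deprivation": {"intercept": -3.0},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``p_base`` is the baseline mixture probability (the cause-1 mass at
    covariates zero as time goes to infinity); ``rho`` sets how much of that
    mass falls before the horizon.  ``period2_rate_multiplier`` < 1 scales
    the subdistribution hazard for period-2 entrants, emulating falling
    mortality.  ``region_sigma`` is the SD of Gaussian region intercepts
    added to both linear predictors.
    """

    n_subjects: int = 20_000
    n_regions: int = 10
    period_boundary: float = 10.0   # calendar years; entries span two decades
    horizon: float = 10.0
    p_base: float = 0.13
    rho: float = 0.25
    beta_sub: dict = field(default_factory=_default_beta_sub)
    beta_competing: dict = field(default_factory=_default_beta_competing)
    competing_base_rate: float = 0.008   # per year at covariates zero
    censor_rate: float = 0.04            # per year, covariate independent
    period2_rate_multiplier: float = 0.75
    region_sigma: float = 0.08
    mar_config: dict = field(default_factory=_default_mar_config)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not (0.0 < self.p_base < 1.0):
            raise ValueError("p_base must lie in (0, 1)")
        if self.n_regions < 2:
            raise ValueError("at least two regions are required")
        if self.period2_rate_multiplier <= 0:
            raise ValueError("period2_rate_multiplier must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if not self.beta_sub or not self.beta_competing:
            raise ValueError("coefficient vectors must be non-empty")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _draw_covariates(n, rng):
    age = np.clip(rng.normal(63.0, 14.0, n), 20.0, 97.0)
    bmi = np.clip(np.exp(rng.normal(np.log(26.5), 0.19, n)), 15.0, 55.0)
    deprivation = rng.normal(-0.6, 2.95, n)
    stage = rng.choice([1, 2, 3, 4], n, p=[0.45, 0.40, 0.09, 0.06])
    grade = rng.choice([1, 2, 3], n, p=[0.16, 0.51, 0.33])
    er = rng.binomial(1, 0.85, n)
    pr = (rng.random(n) < (0.55 + 0.25 * er)).astype(int)
    her2 = rng.binomial(1, 0.15, n)
    route = rng.choice(CATEGORICAL_LEVELS["route"], n, p=[0.30, 0.42, 0.05, 0.23])
    smoking = rng.choice([0, 1, 2], n, p=[0.60, 0.25, 0.15])
    comorbidity = rng.binomial(1, 0.30, n)
    hrt = rng.binomial(1, 0.08, n)
    # treatment auxiliaries: not predictors, imputation-model-only
    chemo = rng.binomial(1, 0.27, n)
    radio = rng.binomial(1, 0.21, n)
    return pd.DataFrame({
        "age": age, "bmi": bmi, "deprivation": deprivation,
        "stage": stage, "grade": grade, "er": er, "pr": pr, "her2": her2,
        "route": route, "smoking": smoking, "comorbidity": comorbidity,
        "hrt": hrt, "chemo": chemo, "radio": radio,
    })


def design_terms(df: pd.DataFrame) -> pd.DataFrame:
    """Standardised generator design terms the coefficient dicts refer to."""
    age_std = (df["age"] - 63.0) / 14.0
    return pd.DataFrame({
        "age_std": age_std,
        "age_std_sq": age_std ** 2 - 1.0,   # centred square
        "bmi_std": (df["bmi"] - 27.0) / 5.5,
        "deprivation_std": (df["deprivation"] + 0.6) / 2.95,
        "stage_num": df["stage"].astype(float) - 1.0,
        "grade_num": df["grade"].astype(float) - 1.0,
        "er": df["er"].astype(float),
        "her2": df["her2"].astype(float),
        "screen_detected": (df["route"] == "screen").astype(float),
        "smoking_num": df["smoking"].astype(float),
        "comorbidity": df["comorbidity"].astype(float),
    })


def _linear_predictor(terms, beta):
    lp = np.zeros(len(terms))
    for name, b in beta.items():
        if name not in terms.columns:
            raise KeyError(f"coefficient refers to unknown term {name!r}")
        lp += b * terms[name].to_numpy()
    return lp


def cause1_cif(t, eta, config: SimConfig):
    """Analytic subdistribution CIF of cause 1 at time ``t`` given eta."""
    base = config.p_base * (1.0 - np.exp(-config.rho * np.asarray(t, float)))
    return 1.0 - (1.0 - base) ** np.exp(eta)


def simulate_event_times(eta1, eta2, config: SimConfig, rng):
    """Draw latent (time, cause) pairs from the Fine-Gray mixture.

    ``eta1`` is the subdistribution linear predictor (cause 1), ``eta2`` the
    log-relative hazard of the competing event.  Returns uncensored latent
    times; censoring is applied by the caller.
    """
    eta1 = np.asarray(eta1, dtype=float)
    eta2 = np.asarray(eta2, dtype=float)
    if not (np.isfinite(eta1).all() and np.isfinite(eta2).all()):
        raise ValueError("linear predictors must be finite")
    n = len(eta1)
    p_inf = 1.0 - (1.0 - config.p_base) ** np.exp(eta1)
    is1 = rng.random(n) < p_inf
    t = np.empty(n)
    # cause 1: inverse transform of the conditional subdistribution
    u = rng.random(n) * p_inf
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = (1.0 - (1.0 - u) ** np.exp(-eta1)) / config.p_base
        t1 = -np.log1p(-inner) / config.rho
    t[is1] = t1[is1]
    # cause 2: exponential with log-linear hazard
    lam2 = config.competing_base_rate * np.exp(eta2)
    t2 = rng.exponential(1.0, n) / lam2
    t[~is1] = t2[~is1]
    cause = np.where(is1, 1, 2)
    return t, cause


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a cohort DataFrame; reproducible given ``config.seed``.

    Columns: id, entry (calendar years), region, period, time, cause,
    covariates, and ``truth`` = the analytic cause-1 CIF at the horizon.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    df = _draw_covariates(n, rng)
    df.insert(0, "id", np.arange(n))
    df["region"] = rng.integers(1, config.n_regions + 1, n)
    df["entry"] = rng.uniform(0.0, 2.0 * config.period_boundary, n)
    df["period"] = np.where(df["entry"] < config.period_boundary, 1, 2)

    u1 = rng.normal(0.0, config.region_sigma, config.n_regions)
    u2 = rng.normal(0.0, config.region_sigma, config.n_regions)
    terms = design_terms(df)
    eta1 = _linear_predictor(terms, config.beta_sub) + u1[df["region"] - 1]
    eta2 = _linear_predictor(terms, config.beta_competing) + u2[df["region"] - 1]
    eta1 = eta1 + np.where(df["period"] == 2,
                           np.log(config.period2_rate_multiplier), 0.0)

    t_latent, cause_latent = simulate_event_times(eta1, eta2, config, rng)
    if config.censor_rate > 0:
        c = rng.exponential(1.0 / config.censor_rate, n)
    else:
        c = np.full(n, np.inf)
    t_obs = np.minimum.reduce([t_latent, c, np.full(n, config.horizon)])
    cause = np.where(t_latent <= np.minimum(c, config.horizon), cause_latent, 0)
    df["time"] = np.maximum(t_obs, 1e-8)
    df["cause"] = cause
    df["truth"] = cause1_cif(config.horizon, eta1, config)
    return df


def inject_missingness(cohort: pd.DataFrame, mar_config=None, seed=0) -> pd.DataFrame:
    """Return a copy with covariates masked missing-at-random.

    Each entry of ``mar_config`` maps a maskable covariate to logit
    coefficients over always-observed conditioning terms (``intercept``,
    ``period1``, ``age_std``, ``comorbidity``).  The input frame is left
    untouched, so the caller retains the complete values for
    imputation-quality checks.
    """
    mar_config = _default_mar_config() if mar_config is None else mar_config
    bad = set(mar_config) - set(MASKABLE)
    if bad:
        raise ValueError(f"not maskable: {sorted(bad)}")
    cond = {
        "intercept": np.ones(len(cohort)),
        "period1": (cohort["period"] == 1).astype(float).to_numpy(),
        "age_std": ((cohort["age"] - 63.0) / 14.0).to_numpy(),
        "comorbidity": cohort["comorbidity"].astype(float).to_numpy(),
    }
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for var, coefs in mar_config.items():
        unknown = set(coefs) - set(cond)
        if unknown:
            raise ValueError(
                f"missingness for {var!r} conditions on non-observed or "
                f"maskable variables: {sorted(unknown)}")
        logit = np.zeros(len(cohort))
        for name, b in coefs.items():
            logit += b * cond[name]
        p = 1.0 / (1.0 + np.exp(-logit))
        mask = rng.random(len(cohort)) < p
        col = out[var].astype(float) if out[var].dtype != object else out[var]
        out[var] = col.where(~mask, other=np.nan)
    return out


def truncate_followup(cohort: pd.DataFrame, period_boundary: float,
                      horizon: float = 10.0):
    """Split into temporally distinct period-1 / period-2 subcohorts.

    Period-1 entrants whose follow-up would cross the calendar boundary are
    administratively censored at the boundary, so the two subcohorts emulate
    wholly separate datasets; both respect the ``horizon`` maximum.
    """
    if (cohort["entry"] >= period_boundary).all():
        raise ValueError("period boundary precedes every entry date")
    p1 = cohort[cohort["period"] == 1].copy()
    p2 = cohort[cohort["period"] == 2].copy()
    room = period_boundary - p1["entry"]
    crosses = p1["time"] > room
    p1.loc[crosses, "time"] = room[crosses]
    p1.loc[crosses, "cause"] = 0
    for part in (p1, p2):
        over = part["time"] > horizon
        part.loc[over, "time"] = horizon
        part.loc[over, "cause"] = 0
        part["time"] = part["time"].clip(lower=1e-8)
    return p1, p2


def write_cohort(cohort: pd.DataFrame, path):
    """Write a cohort as delimited text (empty string encodes missing)."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
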