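import warnings

import numpy as np
import pandas as pd
import pytest

from pseudorisk import SimConfig, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2 000-subject cohort with censoring and competing events."""
    return generate_cohort(SimConfig(n_subjects=2000, n_regions=5, seed=42))


@pytest.fixture(scope="session")
def competing_sample():
    """Random censored competing-risks data (continuous times, n=200)."""
    rng = np.random.default_rng(7)
    time = rng.exponential(5.0, 200) + 1e-4
    cause = rng.choice([0, 1, 2], 200, p=[0.3, 0.45, 0.25])
    return time, cause


def brute_force_pseudovalues(time, cause, tstar, target):
    """Literal O(n^2) leave-one-out recomputation (the reference)."""
    from pseudorisk.nonparametric import aalen_johansen, kaplan_meier

    def estimate(t, c):
        if target == "cif_cause1":
            return float(aalen_johansen(t, c, 1)(tstar))
        return 1.0 - float(kaplan_meier(t, c == 1)(tstar))

    time = np.asarray(time, float)
    cause = np.asarray(cause, int)
    n = len(time)
    full = estimate(time, cause)
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        out[i] = n * full - (n - 1) * estimate(time[mask], cause[mask])
    return out, full
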