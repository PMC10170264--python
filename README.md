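# pseudorisk

Competing-risks prognostic modelling with jack-knife pseudo-observations:
development and internal-external validation of 10-year event-risk models.

## The problem

In cancer prognosis (and many other clinical settings) the quantity of
interest is the probability that a patient dies *of their disease* within a
horizon — say 10 years — while deaths from other causes compete and
follow-up is right-censored. Comparing modelling strategies for this task
fairly requires more than a single train/test split: performance must be
shown to transport across regions and calendar time, and the uncertainty of
that claim quantified.

`pseudorisk` implements a full comparative framework for this problem:

* **Four model-building strategies**, all emitting a 10-year event
  probability:
  * `CoxRiskModel` — Cox proportional hazards (competing deaths censored,
    Efron ties, clustered sandwich errors), risk `1 − S₀^exp(Xβ)`;
  * `PseudoCloglogRisk` — regression of jack-knife pseudo-observations of
    the Aalen–Johansen cumulative incidence function (CIF) at 10 years on
    predictors, with a complementary log-log link and robust errors, so the
    coefficients live on the Fine–Gray subdistribution scale and risk is
    `1 − exp(−exp(Xβ))`;
  * `PseudoXGBRisk` / `PseudoMLPRisk` — gradient boosting and a
    feed-forward network trained on the same pseudo-observation target
    (squared-error loss), predictions clipped to [0, 1]. This is how
    machine learners are adapted to censored competing-risks data without a
    bespoke survival loss.
* **Pseudo-observations.** For an estimator θ̂ of the CIF (or Kaplan–Meier
  failure probability) at the horizon, subject *i*'s pseudo-observation is
  θᵢ = n·θ̂ − (n−1)·θ̂₍₋ᵢ₎. Their mean equals θ̂ exactly, and they serve as a
  per-subject regression target that carries the censoring adjustment. The
  leave-one-out estimates are computed by an O(n) grouped recursion,
  verified against literal recomputation.
* **Missing data.** Chained-equations multiple imputation (predictive mean
  matching) conditioning on the other predictors, the endpoint indicator,
  treatment auxiliaries, the Nelson–Aalen cumulative hazard and the entry
  period; Rubin's rules for pooling, imputation stacking for the machine
  learners.
* **Evaluation.** Harrell's C at the horizon (inverse-probability-of-
  censoring-weighted under competing risks), calibration slope and
  calibration-in-the-large from pseudo-observation GLMs on the cloglog
  scale, smoothed calibration curves, decision-curve net benefit with and
  without competing-risks handling, and crude event rates with log-normal
  intervals.
* **Internal–external cross-validation (IECV).** The cohort is split by
  region × calendar period; models are trained on period-1 data (follow-up
  truncated at the period boundary) with nested hyperparameter tuning, and
  tested on each held-out region's period-2 data. Region-level metrics are
  pooled by Rubin's rules across imputations and by
  Hartung–Knapp–Sidik–Jonkman random-effects meta-analysis across regions,
  with 95% confidence and prediction intervals, τ², I², and meta-regression
  R² against regional case-mix. A hash audit certifies that no test-period
  subject enters any training computation.
* **Synthetic cohorts.** A generator with known ground truth (Fine–Gray
  mixture events, exponential competing hazards and censoring, region
  random intercepts, a lower period-2 rate, missing-at-random gaps) drives
  all tests; every generated subject carries its analytic true risk.

## Worked example

```python
import numpy as np
from pseudorisk import (SimConfig, generate_cohort, jackknife_pseudovalues,
                        PseudoCloglogRisk, hksj_random_effects)
from pseudorisk.cohort import design_terms

cohort = generate_cohort(SimConfig(n_subjects=20_000, seed=1))
pv = jackknife_pseudovalues(cohort["time"], cohort["cause"],
                            tstar=10.0, target="cif_cause1")
print(f"AJ CIF at 10y: {pv.full_sample_estimate:.4f}  "
      f"pseudovalue range: [{pv.min:.3f}, {pv.max:.3f}]")

X = design_terms(cohort)[["age_std", "stage_num", "er"]]
model = PseudoCloglogRisk().fit(X, pv.values)
for name in X.columns:
    print(f"{name:10s} sHR {np.exp(model.coef_[name]):.3f} "
          f"(robust se {model.se_[name]:.3f})")

pooled = hksj_random_effects([0.80, 0.85, 0.90], [0.02, 0.02, 0.02])
print(f"pooled C {pooled.estimate:.3f} "
      f"(95% CI {pooled.ci_low:.3f} to {pooled.ci_high:.3f}; "
      f"95% PI {pooled.pi_low:.3f} to {pooled.pi_high:.3f}; "
      f"I2 {pooled.i2:.0f}%)")
```

Output:

```
AJ CIF at 10y: 0.1805  pseudovalue range: [-0.027, 1.471]
age_std    sHR 1.692 (robust se 0.025)
stage_num  sHR 1.645 (robust se 0.020)
er         sHR 0.617 (robust se 0.046)
pooled C 0.850 (95% CI 0.726 to 0.974; 95% PI 0.162 to 1.538; I2 84%)
```

Reading it: 18.1% of this synthetic cohort dies of the disease within 10
years acknowledging the competing risk; censoring pushes individual
pseudo-observations outside [0, 1], which is expected and harmless. The
cloglog coefficients are subdistribution hazard ratios — risk rises with
age and stage and falls with receptor-positive status. The meta-analysis
line pools three region-level C indices: the confidence interval describes
the average performance, the (much wider) prediction interval the
performance expected in a *new* region.

The same pipeline end to end, from the shell:

```bash
pseudorisk simulate --seed 1 --n 20000 --out cohort.tsv
pseudorisk iecv cohort.tsv --models cox,crr,gbt,ffnn --seed 1 --out report/
pseudorisk report report/
```

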