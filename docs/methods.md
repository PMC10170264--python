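# Methods

This note records the statistical model behind `pseudorisk`, the choices
made where the design was genuinely open, and what the test suite does and
does not establish.

## Outcome model and estimands

Each subject contributes a follow-up time `T` in (0, horizon] and a cause
code: 0 censored, 1 event of interest, 2 competing event. The estimand for
all four modelling strategies is the cause-1 cumulative incidence at the
10-year horizon, `F₁(10 | X)` — the probability of dying of the disease by
10 years acknowledging that other-cause death removes a subject from risk.
The Cox strategy is the deliberate exception: it treats competing deaths as
censoring and therefore targets the cause-specific failure probability
`1 − S₀^exp(Xβ)`; its calibration is judged against Kaplan–Meier failure
pseudo-observations, while the three competing-risks strategies are judged
against Aalen–Johansen CIF pseudo-observations. The two estimands coincide
as competing events become rare (tested: full-model Cox and cloglog
predictions rank-correlate > 0.9 when the competing hazard is negligible).

## Pseudo-observations

For an estimator θ̂ of the CIF (or KM failure) at `t*`, subject `i`'s
jack-knife pseudo-observation is `θᵢ = n·θ̂ − (n−1)·θ̂₍₋ᵢ₎`. Properties the
implementation relies on and the suite verifies:

* mean(θᵢ) = θ̂ exactly (jack-knife identity);
* with complete data the θᵢ reduce to event indicators 1{Tᵢ ≤ t*};
* under censoring the θᵢ leave [0, 1]; the `PseudovalueSet` records the
  min/max for clipping diagnostics.

The leave-one-out estimates are computed in O(n) after sorting: removing a
subject shrinks every risk set before its observation time by one and
adjusts its own tie group's counts, so prefix products of risk-set-shrunk
factors combined with a suffix recursion of unmodified factors yield all n
values in one pass. Tie convention: subjects with identical times form one
group; events and censorings at a tied time are both in the risk set at
that time and censorings leave after the events (the standard product-limit
convention). The literal O(n²) recomputation is the oracle in the tests
(equality to 1e-10 at n = 200, with and without ties).

Pseudo-observations are computed separately within each evaluation stratum:
the full cohort for final-model fitting, each IECV training subset for
training targets, and each held-out region's period-2 subset for
calibration assessment.

## Pseudo-observation regression: the working variance

The cloglog model `F₁(X) = 1 − exp(−exp(Xβ))` is fitted by quasi-likelihood
IRLS with **Gaussian working variance** by default. The binomial working
variance `μ(1−μ)` has an infinite pull as fitted values approach 1, so the
quasi-score diverges whenever a covariate cell's pseudo-observation mean
exceeds 1 — which genuinely happens under heavy censoring near the horizon
(e.g. period-1 data truncated at the period boundary, where the censoring
survival `G(10−)` is tiny and late events carry very large
pseudo-observations). With a Gaussian working variance the fit is a
bounded nonlinear least-squares problem; coefficients remain consistent for
the same mean model and the sandwich (HC1) standard errors remain valid.
`working_variance="binomial"` is available for sensitivity analysis. When
the IRLS flag does not settle (it can oscillate in a ~1e-7 band), the fit
is polished by L-BFGS from the IRLS iterate; a fit is rejected if any
coefficient is non-finite or exceeds 1e8 in magnitude.

Calibration metrics use the same family: the slope is the coefficient of
`cloglog(p̂)` in a pseudo-observation GLM with cloglog link, and
calibration-in-the-large is the intercept of the intercept-only model with
`cloglog(p̂)` as offset (ideals 1 and 0). Predictions are clipped by
ε = 1e-6 before link transforms because clipped machine-learning output can
be exactly 0 or 1.

## Cox strategy

Partial likelihood with Efron tie handling (the `lifelines` default —
accurate with moderate ties at modest cost), optional clustered sandwich
errors, and a Breslow baseline cumulative hazard evaluated at the centred
covariates — continuous predictors centred at their training means, binary
and dummy columns at zero. Across imputations the baseline is pooled on the
cumulative-hazard scale, `S₀ = exp(−mean_j H₀ⱼ)`, since an averaging scale
is not dictated; coefficients and their variances are pooled by Rubin's
rules. A small ridge penalty (1e-4 in the pipeline) stabilises rare dummy
levels in small training folds.

## Fractional polynomials and predictor selection

Continuous predictors may enter through fractional-polynomial bases with
powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log; a repeated power p
contributes `x^p` and `x^p·log x`), at most two powers. Variables are
shifted to positivity and scaled by a power of ten for numerical range.
Selection is by deviance over all FP1/FP2 candidates within the relevant
family — Cox partial likelihood, or for the pseudo-observation family the
Gaussian profile deviance `n·log(RSS/n)` (a true quasi-deviance does not
exist for out-of-range responses) — followed by a closed test at α = 0.05:
best FP2 against linear on 3 df, then FP2 against best FP1 on 2 df. FP
terms are re-selected inside every IECV training fold (on the first
completed dataset), so term selection is honestly nested in the
cross-validation.

Predictor selection applies the magnitude-and-significance rule to the
Rubin-pooled full model: binary/categorical predictors enter when any level
has an exponentiated coefficient > 1.1 or < 0.9 at P < 0.01; continuous
variables and interactions at P < 0.01. Multilevel categoricals enter whole
if any level qualifies (levels cannot enter alone). The rule is a pure,
permutation-invariant function of the pooled coefficient table. At desk
scale this rule is aggressive — with a few thousand training subjects it
can drop genuinely predictive continuous variables — which is the main
reason pooled discrimination in the shipped IECV runs sits below the
generator's oracle C.

## Machine-learning strategies

Both learners regress the CIF pseudo-observations with squared-error loss
on the predictors selected for the cloglog model (dummy-coded; min-max
scaled for the network), and their predictions are clipped to [0, 1].
The gradient booster runs the CPU histogram algorithm. The network is
fully connected with ReLU hidden activations and a single linear output,
trained by Adam with RMSE loss; the learning rate halves after 3 epochs
without improvement of at least 1e-4 and training stops after 5, restoring
the best weights seen. Hyperparameters are tuned by seeded random search
(default budget 15; the tuner interface is pluggable) over the declared
ranges — tree depth 1–6, learning rate 1e-4–0.1 (log), subsample 0.1–0.5,
rounds 1–500, L1/L2/complexity penalties 0–20, column sampling 0.1–0.8 per
tree/level; for the network 1–5 hidden layers, 26–50 units, 1–50 epochs,
initial rate 1e-3–0.1 (log). The default configuration is always the first
candidate, so tuning can never return something worse than the default in
cross-validated RMSE, and a larger budget with the same seed never hurts.

## Multiple imputation

Chained equations via predictive mean matching (5 donors) for every
incomplete variable; donor-based draws automatically yield valid levels for
categorical variables, which is why a single conditional engine suffices.
The imputation model for each incomplete variable conditions on all other
candidate predictors, the endpoint indicator (cause dummies), the treatment
auxiliaries, the subject's Nelson–Aalen cumulative hazard value, region and
entry period; BMI is imputed on the log scale and exponentiated back. The
default is m = 5 imputations with 10 cycles at full scale (the pipeline's
desk-scale runs use m = 2–3 with 2–3 cycles); m is configurable and
registry-scale analyses typically use far more (50 is common).
Rubin's rules use the Barnard–Rubin small-sample
degrees of freedom (complete-data df optional, ∞ by default).

## Internal–external cross-validation

Period-1 entrants have follow-up truncated at the period boundary (status
censored there), making the two periods wholly distinct datasets. The
default split (`geo_temporal`) excludes the held-out region from training
entirely, measuring joint geographic and temporal transfer; `temporal`
trains on all regions' period 1. Imputation runs separately within
period-1 and period-2 data so that no test-period subject can influence any
training computation; the per-fold hash audit of subject ids enforces this
invariant (`total_overlap` must be 0). Region-level metrics are pooled per
imputation by Rubin's rules, then across regions by HKSJ random effects.

## Meta-analysis

DerSimonian–Laird τ²; HKSJ variance `q/((k−1)·Σw)` with `w = 1/(se²+τ²)`;
CI via t with k−1 df; 95% prediction interval `± t_{k−2}·√(τ² + se²_pooled)`
(flagged unavailable for k < 3); I² = max(0, (Q−(k−1))/Q)·100. The
implementation matches an independent reference (R `metafor`, DL + KNHA,
Riley-type PI) to 1e-8 on frozen examples. Meta-regression uses the
generalised method-of-moments residual τ² (E[Q_E] = (k−p) + τ²·tr(P)),
R² = max(0, 100·(1 − τ²_model/τ²_null)) clipped to [0, 100], and residual
I² from the residual Q. Metrics are pooled on their natural scale.

Known limitation: the t-based prediction interval undercovers when k is
small and within-cluster error rivals τ (≈88% at k = 8 with se ≈ τ); the
coverage simulation is run in the τ-dominant regime (k = 10, τ = 0.08,
se ≤ 0.02) where the construction attains its nominal level.

## Discrimination and decision curves

Harrell's C at the horizon uses pairs (case i, any j with `T_j > T_i`),
risk ties counting ½; the competing-risks version adds comparators with an
earlier-or-equal competing event and weights pairs by the inverse censoring
survival, `1/G(tᵢ−)²` and `1/(G(tᵢ−)G(tⱼ−))` — left limits, the standard
convention. Pairs with `G = 0` are dropped with a flag. The standard error
is the U-statistic influence (delta-method) estimator. Both indices equal
exhaustive pair enumeration exactly, and the IPCW index reduces to the
unweighted competing-risks concordance when censoring is absent.

Net benefit at threshold `p_t` is
`P(p̂ ≥ p_t)·[F_high − (1−F_high)·p_t/(1−p_t)]`, with `F_high` the
Aalen–Johansen CIF (competing-risks handling) or KM failure (without) in
the high-risk group; treat-all uses the whole-sample F, treat-none is 0.
Default threshold grid 0.01–0.50 in steps of 0.01.

## The synthetic generator: what it emulates, what it does not

Cause-1 events follow a Fine–Gray mixture:
`P(cause 1 | X) = 1 − (1−p_base)^exp(η)` with
`F₁(t|X) = 1 − (1 − p_base(1 − e^{−ρt}))^exp(η)`, so the cloglog of the
CIF is exactly linear in the design and the cloglog regression is correctly
specified — this is what makes exact coefficient-recovery tests possible.
Cause-2 times are exponential with a log-linear hazard; censoring is
exponential, covariate-independent, plus administrative censoring at the
horizon (satisfying the IPCW assumptions). Gaussian region intercepts
(SD 0.08) create genuine inter-region heterogeneity; period-2 entrants
have the subdistribution rate multiplied by 0.75, emulating falling
mortality. Defaults (`p_base = 0.13`, `ρ = 0.25`, moderate covariate
effects over age, BMI, deprivation, stage, grade, receptor status, route,
smoking, comorbidity) give a ten-year cumulative incidence near 17–19%
with a lower period-2 rate, inside the 10–25% band of the motivating
cohort structure. Missingness is missing-at-random through logistic models
on always-observed variables (age, period, comorbidity), heavier in
period 1, as in registry data.

The generator does **not** attempt the real cohort's covariate marginals
or correlation structure, informative censoring, practice-level
clustering, or measurement error. Passing recovery and calibration tests
therefore shows the estimators are correct under their stated assumptions
— not that the real data meet those assumptions.

A consequence worth knowing when reading IECV output: models trained on
period 1 and tested on period 2 systematically over-predict, and the
pooled calibration-in-the-large sits near `log(0.75) ≈ −0.29` — the
generator's own period effect on the cloglog scale. That is the temporal
transportability gap the design is meant to expose, not a defect.

## Problem sizes

The shipped test suite and acceptance script run at desk scale, chosen as
the package's own reference conditions: pseudo-observation oracles at
n = 200; coefficient-recovery coverage over 100 replicates of n = 4 000;
calibration recovery at n = 50 000; 500 simulated meta-analyses; and a
complete four-model IECV run at n = 10 000 with 10 regions, m = 2
imputations and tuner budget 3. Full-scale defaults (n = 20 000, m = 5,
budget 15) are the library defaults and run in well under an hour on one
CPU.
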