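# Methods

`polybtdm` implements AUC-guided dose individualization for intravenous
polymyxin B: a population pharmacokinetic (PK) simulator, a MAP Bayesian
estimator for sparse therapeutic-drug-monitoring samples, dosing logic
against a steady-state AUC target window, and the exposure–toxicity
meta-regression that fixes the window's upper bound. This note records
the models, the defaults and why, and the places where the design was
genuinely open.

## Disposition model

Drug amounts in central (A1) and peripheral (A2) compartments follow

    dA1/dt = R(t) − (k10 + k12)·A1 + k21·A2
    dA2/dt = k12·A1 − k21·A2,      C(t) = A1/V1

with k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 and R(t) the infusion-rate
profile. The macro exponents α ≥ β > 0 are the eigenvalues of the rate
matrix (α+β = k10+k12+k21, αβ = k10·k21). Concentrations are evaluated
in closed form — the biexponential during-/post-infusion solution,
superposed over all infusion events — not by numeric integration; an
ODE integrator serves only as an independent test oracle (agreement
≤ 1e−6 relative). When α and β coincide to within 1e−10 relative
(possible only in the k12 → 0, k10 → k21 corner), the critically damped
`t·e^{−λt}` limiting form is used.

Units are hours, mg, L, mg/L throughout. Time zero is the start of the
loading infusion; maintenance infusions run on the q12h grid (12, 24,
36 … h). A sample scheduled exactly at a dose time is a pre-dose
trough: the infusion starting at that instant has contributed nothing
yet (this falls out of the closed form, no special-casing).

Steady-state daily AUC uses the linear-PK identity ssAUC₀₋₂₄ =
daily dose / CL, exact regardless of V1, Q, V2 or the shape of the
regimen within the day; adaptive quadrature of the concentration curve
is retained as an oracle (`auc_numeric`).

## Population model

Typical per-kg values, lognormal between-subject variability (BSV) and
linear weight scaling (absolute parameter = per-kg value × weight):

| parameter | typical | BSV (CV) | provenance |
|---|---|---|---|
| CL | 0.0276 L/h/kg | 32.4% | published adult population value |
| V1 | 0.25 L/kg | 30% | representative (see below) |
| Q | 0.06 L/h/kg | 30% | representative |
| V2 | 0.25 L/kg | 30% | representative |

Only clearance (and its BSV) is published for the source population
model; V1, Q and V2 are this package's own choices, picked once to give
Vss ≈ 0.5 L/kg and a terminal half-life of ~12–13 h, consistent with
polymyxin B disposition in critically ill adults. Every steady-state
AUC quantity depends on CL alone; the volumes matter only through the
information content of individual concentration samples, i.e. they
shift the feedback-control attainment numbers by a few points but no
headline identity.

A typical value is interpreted as the **arithmetic mean** of the
lognormal: ω = √ln(1+CV²), log-location = ln(mean) − ω²/2. This is the
interpretation that reproduces the published asymmetric exposure split
under fixed dosing (≈71% within / 19.8% above / 9.2% below the 50–100
window; the closed-form lognormal probabilities are 71.4 / 19.5 / 9.1).
Treating 0.0276 as the median instead would predict ≈70.7 / 21.5 / 7.8
— close, but the mean reading also matches the stated "population mean
clearance".

### Residual (measurement) error

Simulated assays are perturbed as y = f·(1+εp) + εa with εp ~
N(0, 0.10²) and εa ~ N(0, 0.05²) mg/L; negative draws (rare) are
truncated to zero and flagged. The proportional CV of 10% represents
assay-level measurement error — the precision of validated LC–MS/MS
polymyxin B assays — rather than full residual unexplained variability
of a population fit. The magnitude was calibrated by simulation against
the published feedback-control performance: at 10% CV a single 24-h
sample yields ~95–97% window attainment (published: 95.3%), while at
20% CV no estimator variant exceeds ~88%, so 20% is inconsistent with
the source experiment. Both components are configurable
(`residual_proportional_cv`, `residual_additive_sd_mg_L`).

## MAP Bayesian estimator

Estimation works on log-parameters (positivity for free; the lognormal
prior becomes Gaussian). The objective is

    Σ_j [ (y_j − f_j)² / σ_j² + ln σ_j² ]  +  Σ_k [ (ln θ_k − μ_k)² / ω_k² ]

with μ_k the log-median prior centre. Two σ conventions are available:

- **observation weighting** (default for `map_estimate`): σ_j²
  evaluated at the observed y_j, making the ln σ² term a constant. With
  noise-free data the optimum reproduces the generating parameters up
  to prior pull (rich-design clearance recovery ≤ 1%), i.e. the
  estimator is unbiased in the small-error limit.
- **prediction weighting** (extended least squares): σ_j² at the model
  prediction, ln σ² included. The textbook MAP form, but the ln σ²
  gradient does not vanish at a perfect fit; with proportional error it
  systematically pulls predictions down and clearance up (~1–4% on rich
  noise-free designs, more with sparse data at large CV). Retained as
  an option and for the objective-formula oracle tests.

The optimizer is L-BFGS-B with three deterministic starts (ln CL at the
prior centre and ±ω_CL; volumes at their prior centres; objective
tolerance 1e−8); estimation is seed-free and reproducible. All four
parameters are co-estimated under the prior by default
(`estimate_all=False` fixes V1/Q/V2 at typical values — in diagnostics
the two choices gave near-identical clearance estimates, so
co-estimation, the less informative assumption, is the default). With
zero observations the estimate is, by convention, the typical
(arithmetic-mean) parameter set. Parameters with zero BSV are fixed at
their typical values.

With one sample and four parameters the fit is prior-dominated by
construction; the prior regularizes it and no special-casing is needed.
The remaining finite-sample bias of ln CL at the default error
magnitude is ≈ +0.03 (shrinkage of the nuisance volumes leaking into
clearance plus the nonlinearity of the trough-to-clearance map); it is
visible in the feedback simulations as slightly more above-window than
below-window misses.

## Dose individualization

`dose = target_auc × CL_est`, so the predicted ssAUC equals the target
exactly; `auc_ss_daily` and `personalized_daily_dose` are exact
inverses. Doses inside simulations are continuous; a separate
presentation rounding (0.5 mg/kg steps) produces the nominal clinical
dose, e.g. 75 × 0.0276 = 2.07 → 2 mg/kg/day. The window's bounds are
both exposed as computed and as adopted values: the PK/PD lower bound
is (fAUC/MIC 10.0 × MIC 2 mg/L)/(1 − 0.58) = 47.6 mg·h/L, with 50 the
adopted round figure; the toxicity upper bound is the regression
inversion ≈ 99.4, adopted as 100. Window membership is inclusive at
both bounds (boundary mass is measure-zero in simulation).

## Feedback-control simulation

Each virtual subject receives the traditional regimen (2.5 mg/kg over
2 h load, 1.5 mg/kg over 1 h q12h), is sampled on day 1 per the
strategy, MAP-estimated, and re-dosed at midpoint × CL_est; the final
ssAUC is new dose / true CL (the linear-PK identity — no
re-simulation). The zero-sample arm administers the rounded nominal
2 mg/kg/day. Simulations run on a normalized 1-kg subject: dosing is
per-kg and parameters scale linearly with weight, so attainment is
weight-invariant (a weight distribution is available for realism).
Seeding is counter-based off one master seed: the subject stream is
strategy-independent (common random numbers across strategies, which
sharpens the nested-schedule monotonicity comparisons) and the noise
stream is keyed by the sampling times. Non-converged fits (none
observed at defaults) fall back to the best-found point and are
counted — a dosing tool must always emit a dose.

Default study size is 5,000 subjects per strategy, matching the source
experiment; property checks in the test suite use 400–600 subjects with
common random numbers, with Monte-Carlo tolerances sized to the
binomial standard error at that n.

## Nephrotoxicity meta-analysis

Published cohorts are harmonized to cumulative RIFLE-derived grades
(≥25/≥50/≥75% creatinine-clearance decrease); a subject in a higher
grade counts in all lower grades, and grades a study cannot support are
absent (not zero) and dropped listwise. The packaged study table
transcribes the published cohort summaries — 18 rows (one cohort split
into CF and non-CF), 16 with a mappable mild grade. The exposure
metric is the 75th percentile of each cohort's simulated ssAUC₀₋₂₄
distribution; these percentiles are carried as published input data,
because their exact reconstruction depends on unpublished per-study
simulation assumptions (`simulate_study_auc` provides this package's
own reconstruction — fixed central dose, clearance BSV only, 70-kg
default weight when unreported — which lands within ~5% of most
published medians but not all).

The headline fit is weighted least squares of the mild-toxicity rate on
the p75 ssAUC with weights equal to evaluated subjects per cohort
(weighting confirmed by reproducing the published slope to 4
significant figures; other weight columns are selectable, and an
unweighted comparator is provided). The p-value is the two-sided t test
on the slope with n−2 degrees of freedom. Inverting the line at the
maximum acceptable mild-toxicity rate (default 40%) gives the upper
bound, rounded to the nearest 10 mg·h/L for clinical use.

## What the synthetic data do and do not show

The simulator draws independent lognormal parameters, applies linear
weight scaling and i.i.d. assay noise, and assumes the estimation model
equals the generating model. Real patients violate all of this:
renal-function covariates on clearance, parameter correlations,
inter-occasion variability, model misspecification and assay artifacts
are absent. Passing simulations therefore demonstrate the *internal*
consistency and statistical behaviour of the feedback-control machinery
(shrinkage, contraction with added samples, window attainment under the
stated population), not clinical performance. Exact per-strategy
attainment percentages additionally depend on the unpublished volume
parameters and residual magnitude of the source population model, which
is why the package asserts the qualitative structure (single 24-h
sample > 95%, monotone improvement along nested schedules, spread
shrinkage) rather than table rows bit-for-bit.

## Numerical notes

- Eigen-degeneracy threshold 1e−10 relative; variance floor 1e−12 in
  the MAP objective (guards a zero residual spec meeting a zero
  prediction).
- `auc_numeric` splits the integration interval at infusion starts/ends
  (derivative discontinuities) before adaptive quadrature.
- Attainment CVs use the sample SD (ddof=1).
- Optimizer ties broken by first-found (start order: centre, −ω, +ω).
- The regression is invariant to rescaling all weights; the fitted line
  passes through the weighted means to 1e−10.
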