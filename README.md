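# polybtdm

AUC-guided dosing of intravenous polymyxin B by adaptive feedback
control: a population pharmacokinetic (PK) simulator, a MAP Bayesian
clearance estimator for sparse therapeutic-drug-monitoring samples,
dose individualization against a steady-state AUC target window, and
the nephrotoxicity meta-regression that defines the window's upper
bound.

## The problem

Polymyxin B is a last-resort antibiotic for multidrug-resistant
Gram-negative infections with a narrow margin between efficacy and
nephrotoxicity. Because steady-state daily exposure obeys the linear-PK
identity

    ssAUC_0–24 = daily dose / CL,

and clearance (CL) varies ~32% between patients, fixed weight-based
dosing leaves a large fraction of patients outside any exposure target.
This package implements the precision-dosing loop: define a therapeutic
window for ssAUC_0–24 (50–100 mg·h/L — lower bound from murine PK/PD
targets, upper bound from an exposure–toxicity meta-regression), draw
one or more blood samples on day 1, estimate the patient's clearance by
MAP Bayesian fitting under the population prior, and set

    new daily dose = 75 mg·h/L × CL_est,

so the predicted exposure lands at the window midpoint.

## The models

- **Disposition**: linear two-compartment kinetics (CL, V1, Q, V2),
  closed-form biexponential infusion solution with superposition over
  doses. Population values per kg: CL 0.0276 L/h/kg (BSV 32.4%,
  lognormal, arithmetic-mean preserving); V1/Q/V2 are representative
  values giving Vss ≈ 0.5 L/kg.
- **Measurement error**: y = f·(1+εp) + εa with εp ~ N(0, 0.10²),
  εa ~ N(0, 0.05²) mg/L.
- **MAP estimator**: minimizes the penalized log-posterior
  Σ (y−f)²/σ² + Σ (ln θ − μ)²/ω² over log-parameters (L-BFGS-B,
  deterministic multistart).
- **Toxicodynamics**: weighted least squares of the mild-nephrotoxicity
  rate (≥25% creatinine-clearance decrease, RIFLE-harmonized) on the
  75th-percentile ssAUC across 16 published cohorts, weights = cohort
  size; the window's upper bound inverts this line at a 40% acceptable
  rate.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

`examples/03_strategy_evaluation.py` compares "one dose fits all"
against feedback control with one and two day-1 samples (1,000 virtual
subjects, common random numbers):

```
  strategy  within %  above %  below %  AUC CV %
      none      70.7     19.3     10.0      31.9
        24      96.5      3.5      0.0      13.1
     12,24      95.5      4.5      0.0      13.5
```

Without feedback only ~71% of subjects fall inside the 50–100 mg·h/L
window and exposures spread with a 32% CV; a single 24-h trough with
MAP re-dosing lifts attainment above 95% and roughly halves the CV.

`examples/04_nephrotoxicity_meta_analysis.py` reproduces the window
bounds from the packaged study table:

```
18 cohorts; p75 ssAUC median (range): 80.4 (58.9-117.0) mg·h/L
weighted regression (n=16): toxicity % = 5.56 + 0.3466 x ssAUC_p75   (P = 0.0461)
upper bound (40% mild-toxicity cap): 99.4 -> adopted 100 mg·h/L
lower bound: fAUC/MIC 10.0 x MIC 2.0 mg/L = free AUC 20; / (1-0.58) = total AUC 47.6 -> adopted 50 mg·h/L
```

The other examples show a single-patient concentration profile and a
single-patient MAP fit. A thin CLI mirrors the library
(`polybtdm simulate-strategy`, `map-fit`, `recommend-dose`,
`meta-analysis`, `make-fixtures`); run `polybtdm --help`.

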