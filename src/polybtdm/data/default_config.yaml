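# Default polymyxin B adaptive-feedback-control configuration.
# Units are embedded in key names; per-kg values are converted to
# absolute at the population boundary.
population:
  # Published adult typical clearance and its between-subject variability.
  cl_L_h_kg: 0.0276
  cl_bsv_cv: 0.324
  # V1/Q/V2 and their BSV are representative two-compartment values
  # (Vss ~ 0.5 L/kg, terminal half-life ~12-13 h); the source population
  # model does not publish them.
  v1_L_kg: 0.25
  v1_bsv_cv: 0.30
  q_L_h_kg: 0.06
  q_bsv_cv: 0.30
  v2_L_kg: 0.25
  v2_bsv_cv: 0.30
  # Assay-level measurement error applied to simulated concentrations.
  residual_proportional_cv: 0.10
  residual_additive_sd_mg_L: 0.05
regimen:
  loading_dose_mg_kg: 2.5
  loading_duration_h: 2.0
  maintenance_dose_mg_kg: 1.5
  maintenance_duration_h: 1.0
  interval_h: 12.0
window:
  lower_mg_h_L: 50.0
  midpoint_mg_h_L: 75.0
  upper_mg_h_L: 100.0
simulation:
  n_subjects: 5000
  seed: 0
strategies:
  - {label: "none", times_h: []}
  - {label: "12", times_h: [12]}
  - {label: "24", times_h: [24]}
  - {label: "2,12", times_h: [2, 12]}
  - {label: "2,24", times_h: [2, 24]}
  - {label: "4,24", times_h: [4, 24]}
  - {label: "12,24", times_h: [12, 24]}
  - {label: "2,4,12", times_h: [2, 4, 12]}
  - {label: "2,12,24", times_h: [2, 12, 24]}
  - {label: "4,12,24", times_h: [4, 12, 24]}
  - {label: "2,4,12,24", times_h: [2, 4, 12, 24]}
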