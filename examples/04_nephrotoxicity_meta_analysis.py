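"""Exposure-toxicity meta-regression and the therapeutic-window bounds.

Loads the packaged nephrotoxicity study table, fits the weighted
exposure-toxicity line, inverts it at a 40% mild-toxicity cap for the
window's upper bound, and computes the PK/PD-derived lower bound.
"""

from polybtdm import (
    PkpdTargetSpec,
    derive_upper_bound,
    fit_exposure_toxicity,
    load_study_table,
    lower_bound_from_pkpd,
    summarize_percentile_column,
)

studies = load_study_table()
med, lo, hi = summarize_percentile_column(studies, 75)
print(f"{len(studies)} cohorts; p75 ssAUC median (range): {med:.1f} ({lo:.1f}-{hi:.1f}) mg·h/L")

fit = fit_exposure_toxicity(studies)
print(f"weighted regression (n={fit.n_studies}): "
      f"toxicity % = {fit.intercept:.2f} + {fit.slope:.4f} x ssAUC_p75   (P = {fit.p_value:.4f})")

bound = derive_upper_bound(fit, max_acceptable_rate=40.0)
print(f"upper bound (40% mild-toxicity cap): {bound.raw:.1f} -> adopted {bound.rounded:.0f} mg·h/L")

spec = PkpdTargetSpec()
print(f"lower bound: fAUC/MIC {spec.fauc_mic_target} x MIC {spec.mic_breakpoint} mg/L "
      f"= free AUC {spec.free_auc_target:.0f}; / (1-{spec.protein_bound_fraction}) "
      f"= total AUC {lower_bound_from_pkpd(spec):.1f} -> adopted 50 mg·h/L")
print("\nTogether these define the 50-100 mg·h/L ssAUC therapeutic window.")
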