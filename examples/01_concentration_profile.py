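"""Simulate a polymyxin B concentration-time profile for one patient.

Builds the traditional regimen for a 70-kg adult (175 mg loading dose
over 2 h, then 105 mg over 1 h every 12 h), evaluates the closed-form
two-compartment concentration curve, and reports the day-1 trough and
the steady-state daily AUC identity.
"""

import numpy as np

from polybtdm import PKParameters, auc_numeric, auc_ss_daily, concentration, traditional_regimen

params = PKParameters(cl=1.93, v1=17.5, q=4.2, v2=17.5)  # absolute, ~70 kg
regimen = traditional_regimen(weight=70.0, n_doses=30)

for t in [1.0, 2.0, 4.0, 12.0, 13.0, 24.0]:
    print(f"t = {t:5.1f} h   C = {concentration(params, regimen, t):6.2f} mg/L")

daily_dose = 2 * 105.0
auc_quad = auc_numeric(params, regimen, 288.0, 312.0)  # day 13, at steady state
auc_identity = auc_ss_daily(params.cl, daily_dose)
print(f"\nsteady-state AUC(0-24): quadrature {auc_quad:.1f}, "
      f"dose/CL identity {auc_identity:.1f} mg·h/L")
print("(the two agree because AUC at steady state depends only on dose and clearance;")
print(" at 108.8 mg·h/L this patient sits just above the 50-100 window's upper bound")
print(" and is a candidate for a dose reduction)")
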