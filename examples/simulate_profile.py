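"""Simulate a once-daily tobramycin concentration profile.

Builds a typical adult CF patient on the covariate-linked two-compartment
model and prints the concentration at the clinically interesting times of a
once-daily 500-mg course: end of infusion, the standardized peak (30 min
after the end of a 30-min infusion), and the 24-h trough.
"""

from tobramipd import (
    CovariateSet,
    Regimen,
    SupportPoint,
    cmax_mod,
    cmin_24,
    concentration_profile,
    individual_params,
)
from tobramipd.pk import creatinine_for_clcr

# a typical study patient: female, 32 y, 57.5 kg, CLCR 113 mL/min
scr = creatinine_for_clcr(112.7, age=32.4, sex="female", body_weight=57.5)
patient = CovariateSet(age=32.4, sex="female", body_weight=57.5, serum_creatinine=scr)
print(f"patient: {patient.body_weight} kg, CLCR {patient.clcr:.1f} mL/min, "
      f"serum creatinine {patient.serum_creatinine:.0f} µmol/L")

# a plausible parameter vector: V1 = 0.25 L/kg, Ke = 0.01 + 0.003*CLCR
point = SupportPoint(vs=0.25, ki=0.01, ks=0.003, k12=0.6, k21=0.9)
params = individual_params(point, patient)
print(f"individual params: V1 {params.v1:.1f} L, Ke {params.ke:.3f} /h, "
      f"CL {params.clearance:.2f} L/h")

regimen = Regimen.once_daily(500.0, n_doses=1, infusion_duration=0.5)
for t, label in [(0.5, "end of 30-min infusion"), (1.0, "standardized peak time"),
                 (8.0, "8 h"), (24.0, "24-h trough")]:
    c = concentration_profile(params, regimen, [t])[0]
    print(f"C({t:5.1f} h) = {c:6.2f} mg/L   ({label})")

# steady-state standardized exposures (the dosing targets: peak 30-40, trough < 0.5)
print(f"steady-state Cmax_mod = {cmax_mod(params, 500.0):.1f} mg/L "
      f"(target window 30-40 mg/L)")
print(f"steady-state Cmin_24  = {cmin_24(params, 500.0):.3f} mg/L "
      f"(limit < 0.5 mg/L)")
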