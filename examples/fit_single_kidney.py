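"""Fit a mono-exponential time-activity curve to one kidney-cycle.

Three post-therapy scans of a left kidney (hours post-administration, MBq)
are fitted with A(t) = A0 * exp(-lambda t); the fit yields the effective
half-life and, in closed form, the time-integrated activity and the
absorbed dose through the configured S-value.
"""

from stpdosim import (
    SValueConfig,
    TimeActivitySample,
    fit_monoexponential,
    tia_mtp,
    tia_to_dose,
)

samples = [
    TimeActivitySample("P001", 1, "left", t_h=4.0, activity_MBq=93.8),
    TimeActivitySample("P001", 1, "left", t_h=96.0, activity_MBq=31.2),
    TimeActivitySample("P001", 1, "left", t_h=168.0, activity_MBq=12.9),
]

fit = fit_monoexponential(samples)
tia = tia_mtp(fit)
dose = tia_to_dose(tia, SValueConfig(), patient_id="P001", cycle=1, kidney="left")

print(f"A0          = {fit.A0_MBq:.1f} MBq   (activity extrapolated to t=0)")
print(f"T_eff       = {fit.teff_h:.1f} h     (effective half-life)")
print(f"TIA         = {tia.tia_MBq_h:.0f} MBq*h (area under the curve)")
print(f"kidney dose = {dose.dose_Gy:.2f} Gy   (TIA x S-value)")
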