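# Gradual perfusion conditioning: 0.04 -> 0.4 Pa over 3 h in 60-min steps.
# Flow rates are computed from Poiseuille wall shear with the viscosity and
# radius below; the nominal experimental pairing is 0.5 mL/min <-> 0.4 Pa.
medium_viscosity_g_cm_s: 0.0085
lumen_radius_cm: 0.04
n_vessels: 1
start_stress_pa: 0.04
target_stress_pa: 0.4
duration_min: 180
interval_min: 60
mode: gradual_ramping
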