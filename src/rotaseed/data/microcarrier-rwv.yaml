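# Microcarrier bead in a rotating-wall vessel (model validation benchmark)
particle_radius_cm: 0.033
particle_density_g_cm3: 1.3
virtual_mass_coefficient: 0.5
fluid_viscosity_g_cm_s: 0.01
fluid_density_g_cm3: 1.0
lumen_radius_cm: 5.0
vessel_length_cm: 0.0
speed_rph: 2100.0   # 35 rpm
r0_cm: 0.5
theta0_deg: 90.0
revolutions: 8
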