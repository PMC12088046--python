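# Endothelial cell in a rotating TEBV lumen (seeding condition)
particle_radius_cm: 7.5e-4
particle_density_g_cm3: 1.05
virtual_mass_coefficient: 0.5
fluid_viscosity_g_cm_s: 0.0085
fluid_density_g_cm3: 1.0
lumen_radius_cm: 0.04
vessel_length_cm: 1.0
speed_rph: 24.0
r0_cm: 0.02
theta0_deg: 90.0
revolutions: 3
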