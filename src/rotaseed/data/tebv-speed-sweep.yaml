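# Rotation-speed / start-radius sweep over the TEBV seeding condition
particle_radius_cm: 7.5e-4
particle_density_g_cm3: 1.05
virtual_mass_coefficient: 0.5
fluid_viscosity_g_cm_s: 0.0085
fluid_density_g_cm3: 1.0
lumen_radius_cm: 0.04
vessel_length_cm: 1.0
speeds_rph: [15, 20, 24, 30]
start_radii_cm: [0.001, 0.005, 0.01, 0.02]
theta0_deg: 90.0
revolutions: 3
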