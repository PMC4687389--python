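# Calibrated three-zone staining domain for the goose-head adductor transect.
# Positions in millimetres; the muscle layer runs to the closed boundary.

[domain]
length_mm = 30.0
diffusion_coeff_m2_s = 1e-9
boundary_flux = 1.4e-6
initial_concentration_mmol_L = 0.0

[zone.skin]
start_mm = 0.0
end_mm = 0.7
porosity = 0.8
bulk_density_kg_L = 0.16
partition_coeff_L_kg = 200.0

[zone.connective]
start_mm = 0.7
end_mm = 0.8
porosity = 0.8
bulk_density_kg_L = 0.16
partition_coeff_L_kg = 100.0

[zone.muscle]
start_mm = 0.8
end_mm = 30.0
porosity = 0.8
bulk_density_kg_L = 0.265
partition_coeff_L_kg = 200.0

[solver]
n_cells = 600
time_step_s = 60.0
tolerance = 1e-8
flux_convention = total
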