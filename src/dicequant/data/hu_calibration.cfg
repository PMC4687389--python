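# Grayscale anchors from the solution-vial scan (air -> -1000 HU,
# aqueous buffered formalin -> 0 HU) and the molarity conversion constants.

[hu]
gs_air = 12800
gs_water = 18202
k_factor = 4.6
baseline_offset_mmol_L = 150
infiltration_offset_mmol_L = 50
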