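material,grayscale,hu,molarity_mmol_per_L
formalin,18202,0,0
I2KI 1%,21206,394,66
I2KI 3%,24552,949,199
I2KI 6%,28058,1531,398
I2KI 8.8%,31978,2181,583
air,12800,-1000,
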