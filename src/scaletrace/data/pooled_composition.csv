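group,sorted_mass_kg
white_bellied,207.86
black_bellied,31.17
smutsia,7.96
unidentified,0.876
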