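group,sorted_mass_kg,est_mass_kg,est_mass_low_kg,est_mass_high_kg,mni,mni_low,mni_high,pct_of_mni
white_bellied,207.86,127197.3,103571.1,146752.1,717090,583894,827332,89.71
black_bellied,31.17,13015.5,6103.43,28710.8,65434,30684,144341,8.19
smutsia,7.96,49362.75,33360.19,72435.52,16819,11366,24680,2.10
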