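group,cf_kg,n
white_bellied,0.177379827,7
black_bellied,0.198910352,6
smutsia,2.934939652,
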