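race,prevalence
white,0.003
hispanic,0.003
asian,0.001
black,0.002
other,0.002
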