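race,probability
white,0.12
hispanic,0.09
asian,0.03
black,0.05
other,0.1
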