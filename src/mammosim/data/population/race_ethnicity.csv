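level,probability
white,0.4
hispanic,0.38
asian,0.14
black,0.06
other,0.02
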