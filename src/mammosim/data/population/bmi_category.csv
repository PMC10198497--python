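level,probability
underweight,0.03
normal,0.37
overweight,0.3
obese,0.3
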