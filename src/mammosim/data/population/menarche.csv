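level,probability
11,0.12
12,0.25
13,0.3
14,0.2
15,0.09
16,0.04
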