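level,probability
0.0,0.35
12.0,0.13
52.0,0.17
125.0,0.15
260.0,0.1
365.0,0.05
730.0,0.03
1460.0,0.02
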