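level,probability
0,0.19
1,0.19
2,0.35
3,0.17
4,0.1
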