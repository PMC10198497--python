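level,probability
45,0.012325
46,0.029361
47,0.058797
48,0.098981
49,0.140071
50,0.166628
51,0.166628
52,0.140071
53,0.098981
54,0.058797
55,0.029361
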