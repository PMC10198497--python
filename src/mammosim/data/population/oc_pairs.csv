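start,stop
22,44
15,21
20,23
16,32
17,44
20,36
22,44
24,44
17,35
22,33
19,27
16,20
21,42
18,26
21,41
18,38
22,42
17,27
19,44
18,42
20,33
16,34
19,29
22,39
25,44
22,39
25,38
20,31
21,44
26,40
24,44
16,26
23,36
23,34
15,17
21,41
24,44
20,25
19,30
14,38
22,39
14,33
24,35
21,39
14,21
16,33
23,35
21,24
14,29
17,27
22,29
14,21
14,20
21,31
18,26
15,31
20,44
20,29
21,40
23,29
14,31
15,32
22,33
19,24
20,43
21,44
20,44
19,44
19,24
24,33
22,29
25,36
20,37
20,32
23,36
24,38
18,28
24,31
19,40
14,25
14,22
21,30
19,39
14,18
21,34
17,26
18,20
14,25
15,26
16,23
16,26
17,25
14,26
22,41
24,30
22,31
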