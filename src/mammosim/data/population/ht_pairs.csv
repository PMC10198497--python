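start,stop
53,2
48,20
47,3
48,11
51,1
50,4
47,11
53,15
51,9
49,1
50,8
53,1
52,5
47,3
51,7
49,16
50,3
49,5
52,3
50,6
51,18
49,21
54,7
52,4
48,3
48,16
53,6
52,9
50,2
48,2
51,17
52,18
48,3
49,19
50,7
50,9
48,5
50,12
49,18
47,14
52,1
53,15
50,7
47,6
49,17
47,2
48,16
53,5
52,13
52,5
53,4
50,20
52,10
48,1
50,9
50,5
51,8
52,7
53,8
49,20
53,4
48,5
54,7
47,3
54,7
50,14
52,16
52,2
49,19
48,2
51,7
46,2
49,1
51,7
50,5
49,10
46,3
54,5
54,8
45,4
48,10
49,20
49,3
52,6
52,5
51,5
46,6
51,15
50,1
49,11
51,19
54,3
50,4
50,5
52,4
49,8
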