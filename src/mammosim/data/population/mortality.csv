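age,annual_survival
0,0.99998
1,0.999978
2,0.999976
3,0.999973
4,0.999971
5,0.999968
6,0.999964
7,0.999961
8,0.999957
9,0.999952
10,0.999947
11,0.999942
12,0.999936
13,0.999929
14,0.999922
15,0.999914
16,0.999906
17,0.999896
18,0.999885
19,0.999874
20,0.999861
21,0.999847
22,0.999831
23,0.999814
24,0.999795
25,0.999774
26,0.999751
27,0.999726
28,0.999698
29,0.999667
30,0.999633
31,0.999596
32,0.999554
33,0.999509
34,0.999459
35,0.999404
36,0.999343
37,0.999276
38,0.999203
39,0.999121
40,0.999032
41,0.998933
42,0.998825
43,0.998705
44,0.998573
45,0.998428
46,0.998268
47,0.998092
48,0.997898
49,0.997684
50,0.997448
51,0.997189
52,0.996903
53,0.996588
54,0.996241
55,0.995859
56,0.995438
57,0.994975
58,0.994464
59,0.993902
60,0.993283
61,0.992602
62,0.991851
63,0.991025
64,0.990115
65,0.989114
66,0.988011
67,0.986798
68,0.985463
69,0.983995
70,0.982379
71,0.980601
72,0.978647
73,0.976497
74,0.974135
75,0.971538
76,0.968685
77,0.96555
78,0.962109
79,0.95833
80,0.954185
81,0.949637
82,0.944652
83,0.939189
84,0.933206
85,0.926658
86,0.919496
87,0.911669
88,0.903121
89,0.893796
90,0.883632
91,0.872567
92,0.860535
93,0.847469
94,0.833302
95,0.817966
96,0.801395
97,0.783524
98,0.764294
99,0.743651
100,0.721551
101,0.697959
102,0.672857
103,0.646241
104,0.618132
105,0.588574
106,0.557638
107,0.525432
108,0.492094
109,0.457804
110,0.422782
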