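energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,mu_over_rho_cm2_g
4,0,0.391343,0.110664,0.502007
4.10350558,0,0.391188,0.106596,0.497784
4.20968951,0,0.39103,0.102635,0.493665
4.3186211,0,0.390868,0.0987812,0.489649
4.43037145,0,0.390701,0.0950361,0.485737
4.54501349,0,0.390531,0.0913996,0.48193
4.66262206,0,0.390356,0.0878717,0.478228
4.78327391,0,0.390177,0.0844516,0.474629
4.90704779,0,0.389994,0.0811388,0.471133
5.0340245,0,0.389806,0.077932,0.467738
5.16428691,0,0.389613,0.07483,0.464443
5.29792004,0,0.389416,0.0718311,0.461247
5.43501111,0,0.389214,0.0689336,0.458148
5.5756496,0,0.389007,0.0661356,0.455143
5.71992732,0,0.388795,0.063435,0.45223
5.86793842,0,0.388578,0.0608297,0.449407
6.01977951,0,0.388355,0.0583173,0.446673
6.1755497,0,0.388127,0.0558957,0.444023
6.33535067,0,0.387894,0.0535624,0.441456
6.4992867,0,0.387655,0.051315,0.43897
6.66746482,0,0.38741,0.0491511,0.436561
6.83999477,0,0.387159,0.0470684,0.434227
7.01698918,0,0.386902,0.0450644,0.431967
7.19856356,0,0.386639,0.0431367,0.429776
7.38483644,0,0.38637,0.041283,0.427653
7.57592938,0,0.386094,0.039501,0.425595
7.77196713,0,0.385811,0.0377883,0.4236
7.97307762,0,0.385522,0.0361427,0.421665
8.17939213,0,0.385226,0.0345621,0.419788
8.39104531,0,0.384923,0.0330443,0.417967
8.60817531,0,0.384613,0.0315871,0.4162
8.83092386,0,0.384295,0.0301885,0.414484
9.05943633,0,0.38397,0.0288465,0.412816
9.29386189,0,0.383637,0.0275592,0.411196
9.53435353,0,0.383296,0.0263246,0.409621
9.78106823,0,0.382948,0.0251409,0.408089
10.034167,0,0.382591,0.0240063,0.406597
10.2938151,0,0.382226,0.0229189,0.405145
10.5601819,0,0.381852,0.0218772,0.40373
10.8334414,0,0.38147,0.0208795,0.40235
11.1137718,0,0.381079,0.0199241,0.401003
11.4013561,0,0.380679,0.0190094,0.399688
11.6963821,0,0.380269,0.0181339,0.398403
11.9990423,0,0.379851,0.0172962,0.397147
12.3095343,0,0.379422,0.0164948,0.395917
12.6280607,0,0.378984,0.0157284,0.394713
12.9548293,0,0.378536,0.0149955,0.393532
13.2900536,0,0.378078,0.0142948,0.392373
13.6339523,0,0.37761,0.0136251,0.391235
13.9867498,0,0.377131,0.0129852,0.390116
14.3486765,0,0.376641,0.0123738,0.389015
14.7199685,0,0.37614,0.0117898,0.38793
15.1008683,0,0.375629,0.0112321,0.386861
15.4916243,0,0.375105,0.0106997,0.385805
15.8924917,0,0.374571,0.0101913,0.384762
16.3037321,0,0.374024,0.00970618,0.383731
16.7256139,0,0.373466,0.00924321,0.382709
17.1584125,0,0.372896,0.00880149,0.381697
17.6024103,0,0.372313,0.00838012,0.380693
18.0578973,0,0.371717,0.00797822,0.379696
18.5251706,0,0.371109,0.00759496,0.378704
19.0045352,0,0.370488,0.00722953,0.377718
19.496304,0,0.369854,0.00688116,0.376735
20.0007981,0,0.369206,0.00654908,0.375755
20.5183467,0,0.368544,0.0062326,0.374777
21.0492875,0,0.367869,0.00593101,0.3738
21.5939672,0,0.36718,0.00564365,0.372824
22.1527412,0,0.366476,0.00536989,0.371846
22.7259743,0,0.365758,0.00510911,0.370867
23.3140406,0,0.365026,0.00486072,0.369886
23.9173239,0,0.364278,0.00462417,0.368902
24.5362181,0,0.363515,0.00439892,0.367914
25.1711269,0,0.362737,0.00418444,0.366922
25.822465,0,0.361944,0.00398025,0.365924
26.4906573,0,0.361135,0.00378586,0.364921
27.17614,0,0.36031,0.00360083,0.363911
27.8793605,0,0.359469,0.00342473,0.362893
28.6007779,0,0.358611,0.00325713,0.361868
29.3408629,0,0.357737,0.00309763,0.360835
30.1000987,0,0.356846,0.00294587,0.359792
30.8789807,0,0.355939,0.00280148,0.358741
31.6780174,0,0.355015,0.00266411,0.357679
32.4977303,0,0.354073,0.00253342,0.356606
33.3386544,0,0.353114,0.00240911,0.355523
34.2013386,0,0.352137,0.00229087,0.354428
35.086346,0,0.351143,0.00217842,0.353321
35.9942541,0,0.350131,0.00207147,0.352202
36.9256557,0,0.349101,0.00196977,0.35107
37.8811585,0,0.348052,0.00187306,0.349926
38.8613864,0,0.346986,0.00178111,0.348767
39.866979,0,0.345901,0.00169369,0.347595
40.8985927,0,0.344798,0.00161059,0.346408
41.9569008,0,0.343676,0.00153159,0.345207
43.0425941,0,0.342535,0.0014565,0.343991
44.1563813,0,0.341375,0.00138513,0.342761
45.2989893,0,0.340197,0.00131731,0.341514
46.4711638,0,0.339,0.00125286,0.340252
47.67367,0,0.337783,0.00119162,0.338975
48.9072928,0,0.336548,0.00113344,0.337681
50.1728372,0,0.335293,0.00107816,0.336371
51.4711294,0,0.334019,0.00102566,0.335045
52.8030166,0,0.332726,0.000975793,0.333702
54.1693684,0,0.331414,0.000928438,0.332343
55.5710763,0,0.330083,0.000883473,0.330966
57.0090555,0,0.328733,0.000840784,0.329573
58.4842443,0,0.327363,0.000800262,0.328163
59.9976057,0,0.325974,0.000761803,0.326736
61.5501275,0,0.324567,0.00072531,0.325292
63.1428229,0,0.32314,0.000690688,0.323831
64.7767316,0,0.321694,0.000657848,0.322352
66.4529199,0,0.32023,0.000626707,0.320857
68.1724819,0,0.318747,0.000597184,0.319344
69.93654,0,0.317246,0.000569202,0.317815
71.7462455,0,0.315726,0.000542689,0.316268
73.6027797,0,0.314187,0.000517576,0.314705
75.5073543,0,0.312631,0.000493798,0.313125
77.4612125,0,0.311057,0.000471292,0.311528
79.4656294,0,0.309465,0.00045,0.309915
81.5219134,0,0.307855,0.000429864,0.308285
83.6314067,0,0.306229,0.000410833,0.306639
85.795486,0,0.304585,0.000392854,0.304978
88.0155639,0,0.302924,0.00037588,0.3033
90.2930894,0,0.301247,0.000359864,0.301607
92.6295491,0,0.299554,0.000344763,0.299899
95.0264679,0,0.297845,0.000330535,0.298175
97.4854103,0,0.29612,0.00031714,0.296437
100.007981,0,0.29438,0.00030454,0.294684
102.595827,0,0.292624,0.000292698,0.292917
105.250638,0,0.290855,0.00028158,0.291136
107.974145,0,0.289071,0.000271152,0.289342
110.768126,0,0.287273,0.000261383,0.287534
113.634406,0,0.285462,0.000252242,0.285714
116.574855,0,0.283637,0.000243698,0.283881
119.591392,0,0.2818,0.000235724,0.282036
122.685986,0,0.279951,0.000228292,0.280179
125.860657,0,0.27809,0.000221375,0.278311
129.117477,0,0.276218,0.000214948,0.276433
132.458572,0,0.274334,0.000208985,0.274543
135.886122,0,0.272441,0.000203463,0.272644
139.402365,0,0.270537,0.000198358,0.270735
143.009596,0,0.268623,0.000193647,0.268817
146.710169,0,0.266701,0.000189308,0.26689
150.506499,0,0.26477,0.000185319,0.264955
154.401065,0,0.262831,0.000181661,0.263013
158.396408,0,0.260884,0.000178311,0.261063
162.495136,0,0.25893,0.000175252,0.259106
166.699924,0,0.25697,0.000172464,0.257143
171.013517,0,0.255004,0.000169928,0.255173
175.438731,0,0.253031,0.000167628,0.253199
179.978453,0,0.251054,0.000165546,0.25122
184.635646,0,0.249072,0.000163666,0.249236
189.413351,0,0.247086,0.000161972,0.247248
194.314686,0,0.245096,0.00016045,0.245257
199.342849,0,0.243104,0.000159085,0.243263
204.501124,0,0.241108,0.000157865,0.241266
209.792876,0,0.23911,0.000156777,0.239267
215.221559,0,0.237111,0.000155808,0.237267
220.790717,0,0.23511,0.000154948,0.235265
226.503985,0,0.233109,0.000154187,0.233263
232.365092,0,0.231107,0.000153515,0.23126
238.377862,0,0.229105,0.000152922,0.229258
244.546222,0,0.227104,0.000152401,0.227256
250.874197,0,0.225104,0.000151945,0.225256
257.365917,0,0.223105,0.000151545,0.223256
264.025619,0,0.221108,0.000151196,0.221259
270.85765,0,0.219113,0.000150893,0.219264
277.86647,0,0.217121,0.000150629,0.217271
285.056652,0,0.215131,0.0001504,0.215282
292.432891,0,0.213146,0.000150202,0.213296
300,0,0.211163,0.000150031,0.211313
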