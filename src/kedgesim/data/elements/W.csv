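energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,mu_over_rho_cm2_g
4,931.385,0.158785,10.5098,942.054
4.10350558,874.518,0.158722,10.4436,885.12
4.20968951,821.023,0.158658,10.3746,831.556
4.3186211,770.707,0.158592,10.3029,781.168
4.43037145,723.387,0.158525,10.2284,733.774
4.54501349,678.89,0.158456,10.151,689.2
4.66262206,636.959,0.158385,10.0707,647.188
4.78327391,597.528,0.158312,9.98742,607.674
4.90704779,560.471,0.158238,9.90109,570.53
5.0340245,525.645,0.158161,9.81167,535.615
5.16428691,492.924,0.158083,9.71912,502.801
5.29792004,462.136,0.158003,9.6234,471.917
5.43501111,433.227,0.157921,9.52449,442.91
5.5756496,406.087,0.157837,9.42237,415.668
5.71992732,380.599,0.157751,9.31701,390.074
5.86793842,356.668,0.157663,9.20842,366.034
6.01977951,334.21,0.157573,9.09659,343.464
6.1755497,313.137,0.15748,8.98155,322.276
6.33535067,293.366,0.157386,8.86331,302.386
6.4992867,274.817,0.157289,8.74191,283.716
6.66746482,257.417,0.157189,8.61739,266.192
6.83999477,241.096,0.157087,8.48982,249.743
7.01698918,225.789,0.156983,8.35927,234.306
7.19856356,211.435,0.156877,8.22582,219.818
7.38483644,197.974,0.156767,8.08956,206.221
7.57592938,185.354,0.156655,7.95061,193.461
7.77196713,173.521,0.156541,7.8091,181.487
7.97307762,162.428,0.156423,7.66515,170.25
8.17939213,152.03,0.156303,7.51891,159.705
8.39104531,142.284,0.15618,7.37056,149.81
8.60817531,133.151,0.156054,7.22026,140.527
8.83092386,124.594,0.155925,7.06821,131.818
9.05943633,116.547,0.155794,6.91459,123.617
9.29386189,109.001,0.155658,6.75962,115.916
9.53435353,101.937,0.15552,6.60351,108.696
9.78106823,95.327,0.155379,6.44649,101.929
10.034167,89.1315,0.155234,6.28878,95.5755
10.2067903,85.2143,0.155136,6.18323,91.5526
10.2068107,235.348,0.155136,6.18321,241.686
10.2938151,228.876,0.155086,6.13064,235.162
10.5601819,210.804,0.154934,5.97228,216.931
10.8334414,195.503,0.154779,5.81396,201.472
11.1137718,182.397,0.154621,5.65592,188.207
11.4013561,170.133,0.154458,5.4984,175.786
11.5439881,164.456,0.154378,5.42201,170.033
11.5440112,228.834,0.154378,5.422,234.41
11.6963821,220.825,0.154292,5.34165,226.321
11.9990423,206.016,0.154122,5.18589,211.356
12.099788,201.388,0.154066,5.13517,206.677
12.0998122,232.939,0.154066,5.13516,238.228
12.3095343,223.032,0.153948,5.03135,228.218
12.6280607,209.045,0.153771,4.87827,214.078
12.9548293,195.809,0.153589,4.72684,200.689
13.2900536,183.364,0.153403,4.57728,188.095
13.6339523,171.688,0.153213,4.42978,176.271
13.9867498,160.734,0.153019,4.28451,165.172
14.3486765,150.461,0.15282,4.14164,154.755
14.7199685,140.826,0.152617,4.00132,144.98
15.1008683,131.787,0.152409,3.86369,135.803
15.4916243,123.303,0.152197,3.72888,127.184
15.8924917,115.352,0.15198,3.59698,119.101
16.3037321,107.899,0.151758,3.4681,111.519
16.7256139,100.917,0.151532,3.34231,104.411
17.1584125,94.3764,0.1513,3.21966,97.7474
17.6024103,88.2497,0.151064,3.10021,91.501
18.0578973,82.5117,0.150822,2.984,85.6465
18.5251706,77.1381,0.150575,2.87104,80.1597
19.0045352,72.1065,0.150323,2.76134,75.0182
19.496304,67.3956,0.150066,2.65489,70.2006
20.0007981,62.9855,0.149803,2.5517,65.687
20.5183467,58.8568,0.149535,2.45172,61.4581
21.0492875,54.9907,0.149261,2.35494,57.4949
21.5939672,51.3734,0.148981,2.2613,53.7836
22.1527412,47.9891,0.148696,2.17077,50.3086
22.7259743,44.8232,0.148404,2.0833,47.0549
23.3140406,41.8614,0.148107,1.99882,44.0083
23.9173239,39.0907,0.147804,1.91728,41.1558
24.5362181,36.4998,0.147494,1.8386,38.4859
25.1711269,34.0776,0.147179,1.76273,35.9875
25.822465,31.8135,0.146857,1.6896,33.65
26.4906573,29.6975,0.146528,1.61912,31.4631
27.17614,27.7126,0.146194,1.55124,29.41
27.8793605,25.8558,0.145852,1.48588,27.4876
28.6007779,24.1222,0.145504,1.42297,25.6906
29.3408629,22.5035,0.14515,1.36243,24.0111
30.1000987,20.9924,0.144788,1.30419,22.4414
30.8789807,19.5816,0.14442,1.24818,20.9742
31.6780174,18.2646,0.144045,1.19434,19.603
32.4977303,17.0353,0.143663,1.14259,18.3215
33.3386544,15.8878,0.143274,1.09287,17.1239
34.2013386,14.8167,0.142878,1.04511,16.0047
35.086346,13.8171,0.142474,0.999242,14.9588
35.9942541,12.8841,0.142064,0.955206,13.9814
36.9256557,12.0135,0.141646,0.91294,13.0681
37.8811585,11.201,0.14122,0.872382,12.2146
38.8613864,10.4429,0.140788,0.833474,11.4171
39.866979,9.73544,0.140347,0.796158,10.6719
40.8985927,9.07539,0.1399,0.76038,9.97567
41.9569008,8.45957,0.139444,0.726083,9.3251
43.0425941,7.88505,0.138982,0.693215,8.71724
44.1563813,7.34908,0.138511,0.661724,8.14931
45.2989893,6.84827,0.138033,0.631561,7.61786
46.4711638,6.38121,0.137547,0.602676,7.12143
47.67367,5.94571,0.137054,0.575023,6.65778
48.9072928,5.53963,0.136552,0.548554,6.22474
50.1728372,5.16096,0.136043,0.523226,5.82023
51.4711294,4.8075,0.135526,0.498994,5.44202
52.8030166,4.47775,0.135002,0.475818,5.08857
54.1693684,4.16976,0.134469,0.453656,4.75789
55.5710763,3.88287,0.133929,0.432468,4.44927
57.0090555,3.61565,0.133381,0.412216,4.16125
58.4842443,3.36674,0.132826,0.392863,3.89243
59.9976057,3.13489,0.132262,0.374373,3.64153
61.5501275,2.91895,0.131691,0.356711,3.40735
63.1428229,2.71781,0.131112,0.339844,3.18877
64.7767316,2.53048,0.130526,0.323738,2.98474
66.4529199,2.35599,0.129931,0.308363,2.79429
68.1724819,2.19348,0.12933,0.293688,2.6165
69.524932,2.07615,0.128862,0.282861,2.48788
69.5250711,10.6803,0.128862,0.28286,11.0921
69.93654,10.5249,0.128721,0.279684,10.9333
71.7462455,9.87133,0.128104,0.266322,10.2658
73.6027797,9.24395,0.12748,0.253575,9.625
75.5073543,8.64448,0.126848,0.241418,9.01274
77.4612125,8.08383,0.126209,0.229823,8.43986
79.4656294,7.55948,0.125564,0.218768,7.90381
81.5219134,7.07042,0.12491,0.208229,7.40356
83.6314067,6.61267,0.12425,0.198182,6.9351
85.795486,6.18373,0.123583,0.188607,6.49592
88.0155639,5.78183,0.12291,0.179482,6.08422
90.2930894,5.40533,0.122229,0.170788,5.69834
92.6295491,5.04964,0.121542,0.162505,5.33369
95.0264679,4.71697,0.120849,0.154615,4.99243
97.4854103,4.40595,0.120149,0.147099,4.6732
100.007981,4.1152,0.119443,0.139942,4.37458
102.595827,3.8434,0.118731,0.133126,4.09526
105.250638,3.58935,0.118013,0.126636,3.83399
107.974145,3.35188,0.117289,0.120457,3.58963
110.768126,3.12994,0.116559,0.114575,3.36107
113.634406,2.92252,0.115824,0.108976,3.14732
116.574855,2.72867,0.115084,0.103647,2.94741
119.591392,2.54753,0.114339,0.0985749,2.76045
122.685986,2.37828,0.113589,0.0937485,2.58561
125.860657,2.22013,0.112833,0.0891559,2.42212
129.117477,2.07237,0.112074,0.0847861,2.26923
132.458572,1.93432,0.11131,0.0806288,2.12626
135.886122,1.80536,0.110541,0.0766739,1.99258
139.402365,1.68459,0.109769,0.0729118,1.86727
143.009596,1.56937,0.108992,0.0693334,1.74769
146.710169,1.46211,0.108212,0.06593,1.63625
150.506499,1.36225,0.107429,0.0626933,1.53237
154.401065,1.26928,0.106642,0.0596152,1.43554
158.396408,1.18272,0.105852,0.0566884,1.34526
162.495136,1.10213,0.10506,0.0539055,1.26109
166.699924,1.02708,0.104264,0.0512597,1.18261
171.013517,0.957198,0.103466,0.0487444,1.10941
175.438731,0.892118,0.102666,0.0463534,1.04114
179.978453,0.831508,0.101864,0.0440806,0.977452
184.635646,0.775058,0.10106,0.0419205,0.918038
189.413351,0.72248,0.100254,0.0398676,0.862602
194.314686,0.673506,0.0994465,0.0379168,0.81087
199.342849,0.627886,0.0986379,0.0360631,0.762587
204.501124,0.585389,0.0978282,0.0343019,0.717519
209.792876,0.545798,0.0970176,0.0326288,0.675444
215.221559,0.508912,0.0962064,0.0310395,0.636158
220.790717,0.474545,0.0953946,0.02953,0.59947
226.503985,0.442524,0.0945825,0.0280965,0.565203
232.365092,0.412686,0.0937702,0.0267353,0.533192
238.377862,0.384882,0.092958,0.0254429,0.503283
244.546222,0.35897,0.092146,0.0242162,0.475333
250.874197,0.334822,0.0913345,0.0230519,0.449208
257.365917,0.312316,0.0905234,0.021947,0.424786
264.025619,0.291339,0.0897132,0.0208988,0.401951
270.85765,0.271786,0.0889038,0.0199045,0.380594
277.86647,0.253559,0.0880954,0.0189615,0.360616
285.056652,0.236569,0.0872883,0.0180676,0.341924
292.432891,0.220729,0.0864826,0.0172202,0.324432
300,0.205962,0.0856783,0.0164173,0.308057
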