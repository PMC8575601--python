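energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,mu_over_rho_cm2_g
4,968.039,0.158885,10.6701,978.868
4.10350558,909.029,0.158822,10.6033,919.791
4.20968951,853.513,0.158758,10.5339,864.206
4.3186211,801.292,0.158692,10.4616,811.912
4.43037145,752.175,0.158625,10.3866,762.72
4.54501349,705.984,0.158555,10.3086,716.451
4.66262206,662.55,0.158484,10.2277,672.936
4.78327391,621.675,0.158412,10.1438,631.977
4.90704779,583.199,0.158337,10.0568,593.415
5.0340245,547.033,0.158261,9.96663,557.158
5.16428691,513.051,0.158183,9.87333,523.083
5.29792004,481.118,0.158103,9.77683,491.053
5.43501111,451.095,0.158021,9.67709,460.93
5.5756496,422.877,0.157937,9.57409,432.61
5.71992732,396.386,0.157851,9.46782,406.012
5.86793842,371.518,0.157762,9.35826,381.034
6.01977951,348.16,0.157672,9.24543,357.563
6.1755497,326.24,0.15758,9.12933,335.527
6.33535067,305.672,0.157485,9.00998,314.839
6.4992867,286.374,0.157388,8.88742,295.418
6.66746482,268.269,0.157288,8.76169,277.188
6.83999477,251.287,0.157186,8.63285,260.077
7.01698918,235.357,0.157082,8.50098,244.015
7.19856356,220.417,0.156975,8.36614,228.941
7.38483644,206.407,0.156866,8.22845,214.792
7.57592938,193.269,0.156754,8.088,201.514
7.77196713,180.951,0.156639,7.94493,189.053
7.97307762,169.403,0.156522,7.79936,177.359
8.17939213,158.576,0.156402,7.65146,166.384
8.39104531,148.428,0.156279,7.50137,156.085
8.60817531,138.915,0.156153,7.34928,146.421
8.83092386,130.002,0.156024,7.19537,137.353
9.05943633,121.619,0.155892,7.03984,128.815
9.29386189,113.759,0.155757,6.8829,120.798
9.53435353,106.402,0.155618,6.72476,113.283
9.78106823,99.5163,0.155477,6.56567,106.237
10.034167,93.0696,0.155332,6.40583,99.6308
10.2938151,87.0343,0.155184,6.24551,93.435
10.5352897,81.8802,0.155046,6.09977,88.135
10.5353108,219.306,0.155046,6.09976,225.561
10.8334414,203.362,0.154877,5.92435,209.441
11.1137718,189.761,0.154718,5.764,195.68
11.4013561,177.059,0.154555,5.60415,182.817
11.6963821,165.177,0.154389,5.44502,170.776
11.9586882,155.484,0.154242,5.30765,160.946
11.9587121,216.518,0.154242,5.30764,221.98
12.3095343,200.251,0.154045,5.12991,205.535
12.5266875,191.001,0.153924,5.02328,196.178
12.5267125,220.908,0.153924,5.02327,226.086
12.6280607,216.46,0.153868,4.97438,221.589
12.9548293,202.924,0.153686,4.8205,207.898
13.2900536,190.133,0.1535,4.66848,194.955
13.6339523,178.055,0.153309,4.51851,182.726
13.9867498,166.72,0.153115,4.37077,171.244
14.3486765,156.087,0.152916,4.22544,160.465
14.7199685,146.114,0.152713,4.08268,150.35
15.1008683,136.762,0.152505,3.94261,140.857
15.4916243,127.992,0.152293,3.80538,131.95
15.8924917,119.762,0.152076,3.6711,123.585
16.3037321,112.046,0.151854,3.53985,115.738
16.7256139,104.815,0.151627,3.41172,108.378
17.1584125,98.0395,0.151396,3.28678,101.478
17.6024103,91.6919,0.151159,3.16507,95.0081
18.0578973,85.7458,0.150917,3.04663,88.9433
18.5251706,80.1763,0.15067,2.93149,83.2584
19.0045352,74.9602,0.150418,2.81966,77.9303
19.496304,70.0757,0.15016,2.71113,72.937
20.0007981,65.5022,0.149897,2.6059,68.258
20.5183467,61.2204,0.149629,2.50394,63.874
21.0492875,57.2121,0.149355,2.40522,59.7667
21.5939672,53.4582,0.149075,2.30971,55.917
22.1527412,49.9454,0.148789,2.21735,52.3116
22.7259743,46.6588,0.148498,2.1281,48.9353
23.3140406,43.5839,0.1482,2.04189,45.774
23.9173239,40.7075,0.147897,1.95868,42.8141
24.5362181,38.0162,0.147587,1.87839,40.0422
25.1711269,35.4995,0.147271,1.80095,37.4478
25.822465,33.1464,0.146949,1.7263,35.0197
26.4906573,30.9467,0.146621,1.65436,32.7477
27.17614,28.883,0.146286,1.58507,30.6143
27.8793605,26.9521,0.145944,1.51834,28.6164
28.6007779,25.1489,0.145596,1.4541,26.7486
29.3408629,23.4651,0.145241,1.39229,25.0026
30.1000987,21.8928,0.14488,1.33282,23.3705
30.8789807,20.4247,0.144511,1.27564,21.8449
31.6780174,19.054,0.144136,1.22065,20.4188
32.4977303,17.7742,0.143753,1.16781,19.0858
33.3386544,16.5795,0.143364,1.11702,17.8399
34.2013386,15.4642,0.142968,1.06824,16.6754
35.086346,14.423,0.142564,1.02139,15.587
35.9942541,13.4512,0.142153,0.976415,14.5697
36.9256557,12.5441,0.141735,0.93324,13.619
37.8811585,11.6974,0.141309,0.891809,12.7305
38.8613864,10.9073,0.140876,0.852062,11.9002
39.866979,10.1699,0.140436,0.81394,11.1242
40.8985927,9.48172,0.139988,0.777385,10.3991
41.9569008,8.83958,0.139532,0.742344,9.72146
43.0425941,8.24041,0.139069,0.708761,9.08824
44.1563813,7.68136,0.138598,0.676584,8.49654
45.2989893,7.15978,0.13812,0.645762,7.94366
46.4711638,6.67257,0.137634,0.616244,7.42644
47.67367,6.21793,0.13714,0.587984,6.94305
48.9072928,5.79397,0.136638,0.560934,6.49154
50.1728372,5.39862,0.136129,0.535048,6.0698
51.4711294,5.02997,0.135612,0.510282,5.67587
52.8030166,4.68591,0.135087,0.486593,5.30759
54.1693684,4.36507,0.134554,0.46394,4.96356
55.5710763,4.06516,0.134014,0.442282,4.64146
57.0090555,3.78571,0.133465,0.42158,4.34076
58.4842443,3.52539,0.132909,0.401796,4.0601
59.9976057,3.2829,0.132346,0.382893,3.79814
61.5501275,3.05702,0.131774,0.364837,3.55363
63.1428229,2.84661,0.131195,0.347592,3.3254
64.7767316,2.65062,0.130608,0.331126,3.11235
66.4529199,2.46806,0.130013,0.315406,2.91348
68.1724819,2.29802,0.129411,0.300401,2.72784
69.93654,2.13964,0.128802,0.286081,2.55453
71.6763276,1.99757,0.128208,0.272928,2.3987
71.6764709,10.182,0.128208,0.272927,10.5832
73.6027797,9.53541,0.12756,0.259384,9.92235
75.5073543,8.93267,0.126928,0.246952,9.30655
77.4612125,8.34759,0.126289,0.235095,8.70898
79.4656294,7.80236,0.125643,0.223789,8.15179
81.5219134,7.29897,0.124989,0.213011,7.63697
83.6314067,6.82898,0.124329,0.202736,7.15605
85.795486,6.38834,0.123661,0.192943,6.70495
88.0155639,5.97527,0.122987,0.183611,6.28187
90.2930894,5.58811,0.122306,0.174719,5.88513
92.6295491,5.22527,0.121619,0.166247,5.51314
95.0264679,4.88249,0.120925,0.158176,5.16159
97.4854103,4.56111,0.120225,0.150489,4.83182
100.007981,4.26065,0.119518,0.143168,4.52334
102.595827,3.97976,0.118805,0.136196,4.23477
105.250638,3.71719,0.118087,0.129558,3.96483
107.974145,3.47175,0.117363,0.123237,3.71235
110.768126,3.24233,0.116633,0.11722,3.47618
113.634406,3.0279,0.115897,0.111492,3.25529
116.574855,2.8275,0.115157,0.106041,3.04869
119.591392,2.64021,0.114411,0.100853,2.85547
122.685986,2.46518,0.11366,0.095915,2.67476
125.860657,2.30163,0.112905,0.0912167,2.50575
129.117477,2.14881,0.112144,0.0867463,2.3477
132.458572,2.00601,0.11138,0.0824932,2.19989
135.886122,1.8726,0.110611,0.0784471,2.06166
139.402365,1.74797,0.109838,0.0745982,1.9324
143.009596,1.63153,0.109061,0.0709371,1.81153
146.710169,1.52038,0.108281,0.0674551,1.69611
150.506499,1.41664,0.107497,0.0641435,1.58828
154.401065,1.32006,0.106709,0.0609944,1.48776
158.396408,1.23013,0.105919,0.0579998,1.39405
162.495136,1.1464,0.105126,0.0551525,1.30668
166.699924,1.06843,0.10433,0.0524453,1.2252
171.013517,0.995816,0.103531,0.0498717,1.14922
175.438731,0.928193,0.102731,0.0474252,1.07835
179.978453,0.865211,0.101928,0.0450997,1.01224
184.635646,0.80655,0.101123,0.0428894,0.950563
189.413351,0.751909,0.100317,0.0407888,0.893015
194.314686,0.701011,0.0995091,0.0387926,0.839313
199.342849,0.653596,0.0987,0.0368958,0.789192
204.501124,0.609423,0.0978898,0.0350936,0.742406
209.792876,0.568269,0.0970787,0.0333815,0.698729
215.221559,0.529924,0.096267,0.0317551,0.657946
220.790717,0.494196,0.0954547,0.0302103,0.619861
226.503985,0.460903,0.0946421,0.0287433,0.584288
232.365092,0.429878,0.0938293,0.0273503,0.551058
238.377862,0.400965,0.0930166,0.0260277,0.520009
244.546222,0.374019,0.0922041,0.0247721,0.490995
250.874197,0.348904,0.091392,0.0235805,0.463876
257.365917,0.325494,0.0905805,0.0224496,0.438524
264.025619,0.303674,0.0897697,0.0213767,0.41482
270.85765,0.283332,0.0889598,0.0203589,0.392651
277.86647,0.264369,0.088151,0.0193937,0.371914
285.056652,0.24669,0.0873433,0.0184786,0.352512
292.432891,0.230207,0.0865371,0.0176111,0.334355
300,0.214838,0.0857323,0.0167891,0.31736
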