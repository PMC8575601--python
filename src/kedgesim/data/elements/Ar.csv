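energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,mu_over_rho_cm2_g
4,757.595,0.177744,2.39874,760.171
4.10350558,708.664,0.177674,2.36531,711.207
4.20968951,662.811,0.177602,2.33103,665.319
4.3186211,619.85,0.177528,2.29593,622.323
4.43037145,579.564,0.177453,2.26003,582.002
4.54501349,541.795,0.177375,2.22335,544.195
4.66262206,506.387,0.177296,2.18592,508.75
4.78327391,473.199,0.177215,2.14777,475.524
4.90704779,442.103,0.177131,2.10893,444.389
5.0340245,412.972,0.177046,2.06945,415.219
5.16428691,385.689,0.176959,2.02937,387.895
5.29792004,360.14,0.176869,1.98874,362.305
5.43501111,336.22,0.176777,1.94759,338.344
5.5756496,313.829,0.176683,1.906,315.912
5.71992732,292.873,0.176587,1.864,294.914
5.86793842,273.265,0.176488,1.82165,275.263
6.01977951,254.921,0.176387,1.77903,256.876
6.1755497,237.758,0.176284,1.73618,239.671
6.33535067,221.709,0.176178,1.69318,223.579
6.4992867,206.677,0.176069,1.65009,208.503
6.66746482,192.614,0.175958,1.60696,194.397
6.83999477,179.481,0.175844,1.56388,181.221
7.01698918,167.218,0.175727,1.52091,168.914
7.19856356,155.769,0.175608,1.4781,157.423
7.38483644,145.082,0.175485,1.43553,146.693
7.57592938,135.108,0.17536,1.39326,136.677
7.77196713,125.8,0.175232,1.35135,127.327
7.97307762,117.116,0.175101,1.30986,118.601
8.17939213,109.015,0.174966,1.26885,110.459
8.39104531,101.458,0.174828,1.22837,102.862
8.60817531,94.4112,0.174687,1.18847,95.7744
8.83092386,87.8402,0.174543,1.1492,89.164
9.05943633,81.695,0.174395,1.1106,82.98
9.29386189,75.9625,0.174244,1.07272,77.2095
9.53435353,70.6239,0.17409,1.03558,71.8336
9.78106823,65.6527,0.173931,0.999226,66.8259
10.034167,61.0242,0.173769,0.963676,62.1616
10.2938151,56.7152,0.173603,0.928955,57.8178
10.5601819,52.7042,0.173434,0.895083,53.7727
10.8334414,48.971,0.17326,0.862075,50.0063
11.1137718,45.4968,0.173082,0.829942,46.4998
11.4013561,42.264,0.172901,0.798692,43.2356
11.6963821,39.2561,0.172715,0.76833,40.1972
11.9990423,36.458,0.172525,0.738855,37.3693
12.3095343,33.8551,0.17233,0.710266,34.7377
12.6280607,31.4344,0.172131,0.682559,32.2891
12.9548293,29.1832,0.171928,0.655725,30.0108
13.2900536,27.0899,0.171719,0.629755,27.8914
13.6339523,25.1437,0.171507,0.604639,25.9199
13.9867498,23.3317,0.171289,0.580361,24.0834
14.3486765,21.642,0.171067,0.556908,22.3699
14.7199685,20.0728,0.170839,0.534264,20.7779
15.1008683,18.6157,0.170607,0.512411,19.2987
15.4916243,17.2629,0.170369,0.491331,17.9246
15.8924917,16.0069,0.170126,0.471007,16.648
16.3037321,14.841,0.169878,0.451418,15.4623
16.7256139,13.7587,0.169625,0.432546,14.3609
17.1584125,12.7542,0.169366,0.414371,13.338
17.6024103,11.822,0.169101,0.396873,12.388
18.0578973,10.957,0.16883,0.380033,11.5058
18.5251706,10.1543,0.168554,0.36383,10.6867
19.0045352,9.40957,0.168272,0.348246,9.92609
19.496304,8.71867,0.167984,0.333262,9.21992
20.0007981,8.07777,0.16769,0.318858,8.56432
20.5183467,7.4833,0.167389,0.305015,7.9557
21.0492875,6.93194,0.167083,0.291717,7.39074
21.5939672,6.42063,0.16677,0.278944,6.86634
22.1527412,5.94649,0.16645,0.266679,6.37961
22.7259743,5.50686,0.166124,0.254905,5.92788
23.3140406,5.09926,0.165791,0.243605,5.50866
23.9173239,4.7214,0.165452,0.232764,5.11962
24.5362181,4.37114,0.165105,0.222365,4.75862
25.1711269,4.0465,0.164752,0.212393,4.42364
25.822465,3.74562,0.164391,0.202832,4.11285
26.4906573,3.4668,0.164024,0.193669,3.82449
27.17614,3.20842,0.163649,0.184888,3.55695
27.8793605,2.96901,0.163267,0.176476,3.30875
28.6007779,2.74722,0.162878,0.16842,3.07851
29.3408629,2.54176,0.162481,0.160706,2.86495
30.1000987,2.35145,0.162076,0.153321,2.66685
30.8789807,2.17519,0.161664,0.146254,2.48311
31.6780174,2.01195,0.161244,0.139492,2.31269
32.4977303,1.8608,0.160817,0.133024,2.15464
33.3386544,1.72084,0.160381,0.126837,2.00806
34.2013386,1.59126,0.159937,0.120922,1.87212
35.086346,1.4713,0.159486,0.115268,1.74606
35.9942541,1.36026,0.159026,0.109864,1.62915
36.9256557,1.25749,0.158558,0.1047,1.52074
37.8811585,1.16237,0.158082,0.0997672,1.42022
38.8613864,1.07434,0.157598,0.0950556,1.327
39.866979,0.992894,0.157105,0.0905563,1.24055
40.8985927,0.917533,0.156604,0.0862606,1.1604
41.9569008,0.847814,0.156094,0.0821601,1.08607
43.0425941,0.783319,0.155576,0.0782467,1.01714
44.1563813,0.723664,0.155049,0.0745124,0.953226
45.2989893,0.668489,0.154514,0.0709496,0.893953
46.4711638,0.617463,0.15397,0.0675512,0.838985
47.67367,0.570279,0.153418,0.06431,0.788007
48.9072928,0.526652,0.152857,0.0612192,0.740728
50.1728372,0.486317,0.152287,0.0582724,0.696876
51.4711294,0.449029,0.151708,0.0554631,0.6562
52.8030166,0.414561,0.151121,0.0527855,0.618467
54.1693684,0.382703,0.150525,0.0502336,0.583462
55.5710763,0.35326,0.149921,0.047802,0.550983
57.0090555,0.326052,0.149307,0.0454852,0.520845
58.4842443,0.300911,0.148685,0.043278,0.492875
59.9976057,0.277683,0.148054,0.0411756,0.466913
61.5501275,0.256224,0.147415,0.0391732,0.442812
63.1428229,0.236401,0.146767,0.0372663,0.420434
64.7767316,0.218091,0.146111,0.0354505,0.399652
66.4529199,0.201181,0.145445,0.0337216,0.380348
68.1724819,0.185564,0.144772,0.0320756,0.362411
69.93654,0.171143,0.14409,0.0305088,0.345742
71.7462455,0.157828,0.1434,0.0290174,0.330245
73.6027797,0.145536,0.142701,0.027598,0.315835
75.5073543,0.134188,0.141994,0.0262472,0.302429
77.4612125,0.123714,0.141279,0.0249617,0.289954
79.4656294,0.114046,0.140556,0.0237386,0.27834
81.5219134,0.105124,0.139825,0.0225749,0.267524
83.6314067,0.0968905,0.139086,0.0214678,0.257444
85.795486,0.0892937,0.138339,0.0204146,0.248048
88.0155639,0.0822847,0.137585,0.0194128,0.239283
90.2930894,0.0758188,0.136824,0.01846,0.231102
92.6295491,0.0698544,0.136054,0.0175538,0.223463
95.0264679,0.0643531,0.135278,0.016692,0.216323
97.4854103,0.0592794,0.134495,0.0158725,0.209647
100.007981,0.0546006,0.133704,0.0150932,0.203398
102.595827,0.0502864,0.132907,0.0143523,0.197546
105.250638,0.0463087,0.132103,0.013648,0.19206
107.974145,0.0426416,0.131293,0.0129784,0.186913
110.768126,0.0392611,0.130477,0.0123419,0.18208
113.634406,0.0361453,0.129654,0.0117369,0.177536
116.574855,0.0332735,0.128825,0.0111619,0.173261
119.591392,0.0306271,0.127991,0.0106154,0.169234
122.685986,0.0281884,0.127151,0.0100962,0.165436
125.860657,0.0259415,0.126306,0.00960284,0.16185
129.117477,0.0238715,0.125455,0.00913413,0.158461
132.458572,0.0219645,0.1246,0.00868886,0.155253
135.886122,0.020208,0.12374,0.00826593,0.152214
139.402365,0.0185901,0.122875,0.00786425,0.14933
143.009596,0.0171002,0.122006,0.00748282,0.146589
146.710169,0.0157282,0.121133,0.00712065,0.143982
150.506499,0.0144649,0.120256,0.00677683,0.141498
154.401065,0.0133018,0.119375,0.00645047,0.139128
158.396408,0.0122311,0.118491,0.00614075,0.136863
162.495136,0.0112455,0.117604,0.00584687,0.134696
166.699924,0.0103383,0.116713,0.00556808,0.13262
171.013517,0.00950346,0.11582,0.00530366,0.130627
175.438731,0.00873518,0.114924,0.00505294,0.128713
179.978453,0.00802824,0.114026,0.00481525,0.12687
184.635646,0.00737781,0.113126,0.00459,0.125094
189.413351,0.00677944,0.112224,0.00437659,0.12338
194.314686,0.00622901,0.11132,0.00417447,0.121724
199.342849,0.00572272,0.110415,0.00398311,0.120121
204.501124,0.00525709,0.109509,0.00380201,0.118568
209.792876,0.00482888,0.108602,0.0036307,0.117061
215.221559,0.00443513,0.107694,0.00346872,0.115597
220.790717,0.0040731,0.106785,0.00331565,0.114174
226.503985,0.00374027,0.105876,0.00317106,0.112787
232.365092,0.00343431,0.104966,0.00303458,0.111435
238.377862,0.00315308,0.104057,0.00290583,0.110116
244.546222,0.0028946,0.103148,0.00278445,0.108827
250.874197,0.00265706,0.10224,0.00267012,0.107567
257.365917,0.00243878,0.101332,0.00256251,0.106333
264.025619,0.00223822,0.100425,0.00246131,0.105125
270.85765,0.00205396,0.099519,0.00236623,0.103939
277.86647,0.00188469,0.0986141,0.00227698,0.102776
285.056652,0.0017292,0.0977107,0.0021933,0.101633
292.432891,0.00158639,0.0968087,0.00211494,0.10051
300,0.00145524,0.0959084,0.00204163,0.0994053
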