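energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,mu_over_rho_cm2_g
4,340.469,0.164747,7.58066,348.214
4.10350558,318.758,0.164682,7.52239,326.445
4.20968951,298.407,0.164616,7.46193,306.034
4.3186211,279.333,0.164547,7.39924,286.897
4.43037145,261.458,0.164477,7.33427,268.956
4.55709526,243.027,0.164398,7.25988,250.451
4.55710438,795.606,0.164398,7.25987,803.03
4.66262206,738.337,0.164332,7.19739,745.698
4.78327391,681.158,0.164257,7.12543,688.448
4.85209504,655.881,0.164214,7.08415,663.13
4.85210475,913.757,0.164214,7.08414,921.005
4.90704779,884.56,0.164179,7.05108,891.775
5.0340245,822.285,0.1641,6.97434,829.423
5.18809467,757.66,0.164005,6.88069,764.704
5.18810505,874.394,0.164004,6.88068,881.438
5.29792004,829.512,0.163936,6.81364,836.49
5.43501111,777.734,0.163851,6.72969,784.627
5.5756496,729.021,0.163764,6.64336,735.828
5.71992732,683.225,0.163675,6.55465,689.943
5.86793842,640.18,0.163583,6.46361,646.807
6.01977951,599.677,0.16349,6.37028,606.211
6.1755497,561.607,0.163394,6.27468,568.045
6.33535067,525.853,0.163295,6.1769,532.193
6.4992867,492.253,0.163195,6.07698,498.493
6.66746482,460.727,0.163092,5.975,466.865
6.83999477,431.142,0.162986,5.87106,437.176
7.01698918,403.387,0.162878,5.76524,409.315
7.19856356,377.363,0.162767,5.65766,383.183
7.38483644,352.965,0.162654,5.54842,358.676
7.57592938,330.096,0.162538,5.43765,335.696
7.77196713,308.663,0.162419,5.32548,314.151
7.97307762,288.58,0.162297,5.21206,293.954
8.17939213,269.763,0.162172,5.09753,275.023
8.39104531,252.137,0.162045,4.98205,257.281
8.60817531,235.629,0.161914,4.86578,240.657
8.83092386,220.17,0.16178,4.7489,225.08
9.05943633,205.674,0.161644,4.63157,210.468
9.29386189,192.085,0.161503,4.51397,196.761
9.53435353,179.372,0.16136,4.39629,183.93
9.78106823,167.478,0.161213,4.27869,171.918
10.034167,156.347,0.161063,4.16137,160.669
10.2938151,145.943,0.160909,4.04449,150.148
10.5601819,136.211,0.160752,3.92825,140.3
10.8334414,127.113,0.160591,3.81281,131.087
11.1137718,118.614,0.160426,3.69834,122.473
11.4013561,110.675,0.160258,3.585,114.42
11.6963821,103.259,0.160086,3.47295,106.892
11.9990423,96.3313,0.159909,3.36233,99.8536
12.3095343,89.8617,0.159729,3.25329,93.2747
12.6280607,83.8202,0.159545,3.14596,87.1257
12.9548293,78.179,0.159356,3.04045,81.3788
13.2900536,72.9119,0.159163,2.93688,76.008
13.6339523,67.9946,0.158966,2.83534,70.9889
13.9867498,63.4041,0.158764,2.73592,66.2988
14.3486765,59.1191,0.158558,2.6387,61.9163
14.7199685,55.1194,0.158347,2.54373,57.8215
15.1008683,51.3865,0.158132,2.45108,53.9957
15.4916243,47.9028,0.157912,2.36078,50.4215
15.8924917,44.6518,0.157687,2.27287,47.0824
16.3037321,41.6183,0.157457,2.18736,43.9631
16.7256139,38.7873,0.157222,2.10428,41.0488
17.1584125,36.146,0.156981,2.02362,38.3266
17.6024103,33.6819,0.156736,1.94538,35.784
18.0578973,31.383,0.156485,1.86954,33.4091
18.5251706,29.2389,0.156229,1.7961,31.1913
19.0045352,27.2394,0.155968,1.72501,29.1203
19.496304,25.3747,0.155701,1.65625,27.1866
20.0007981,23.6353,0.155428,1.58979,25.3805
20.5183467,22.013,0.15515,1.52558,23.6938
21.0492875,20.5008,0.154865,1.46358,22.1192
21.5939672,19.0904,0.154575,1.40375,20.6487
22.1527412,17.776,0.154279,1.34603,19.2763
22.7259743,16.5509,0.153977,1.29038,17.9953
23.3140406,15.4091,0.153668,1.23674,16.7995
23.9173239,14.3454,0.153354,1.18506,15.6839
24.5362181,13.3546,0.153033,1.13529,14.6429
25.1711269,12.4316,0.152705,1.08737,13.6717
25.822465,11.5718,0.152371,1.04125,12.7655
26.4906573,10.771,0.15203,0.996876,11.9199
27.17614,10.0196,0.151683,0.954195,11.1255
27.8793605,9.31819,0.151329,0.913154,10.3827
28.6007779,8.66577,0.150968,0.873702,9.69044
29.3408629,8.05893,0.1506,0.835787,9.04532
30.1000987,7.49449,0.150225,0.799361,8.44407
30.8789807,6.96948,0.149843,0.764374,7.88369
31.6780174,6.48114,0.149454,0.730777,7.36138
32.4977303,6.02693,0.149057,0.698526,6.87451
33.1693661,5.68621,0.148735,0.673639,6.50858
33.1694324,35.1841,0.148735,0.673637,36.0064
33.3386544,34.7168,0.148654,0.667573,35.533
34.2013386,32.4613,0.148243,0.637874,33.2475
35.086346,30.3531,0.147824,0.609386,31.1104
35.9942541,28.3843,0.147398,0.582067,29.1137
36.9256557,26.539,0.146964,0.555874,27.2419
37.8811585,24.8099,0.146523,0.53077,25.4872
38.8613864,23.1899,0.146074,0.506713,23.8427
39.866979,21.6723,0.145617,0.483666,22.3015
40.8985927,20.2508,0.145153,0.461593,20.8576
41.9569008,18.9196,0.14468,0.440457,19.5048
43.0425941,17.6732,0.1442,0.420224,18.2376
44.1563813,16.5045,0.143712,0.400859,17.0491
45.2989893,15.4108,0.143216,0.382331,15.9363
46.4711638,14.3874,0.142712,0.364606,14.8947
47.67367,13.4301,0.1422,0.347654,13.9199
48.9072928,12.5346,0.14168,0.331445,13.0077
50.1728372,11.6971,0.141152,0.315951,12.1542
51.4711294,10.914,0.140615,0.301141,11.3558
52.8030166,10.1819,0.140071,0.286991,10.6089
54.1693684,9.4974,0.139519,0.273472,9.91039
55.5710763,8.85764,0.138958,0.26056,9.25716
57.0090555,8.25975,0.13839,0.248229,8.64637
58.4842443,7.70108,0.137813,0.236456,8.07535
59.9976057,7.17912,0.137229,0.225218,7.54157
61.5501275,6.69154,0.136636,0.214492,7.04267
63.1428229,6.23614,0.136035,0.204258,6.57644
64.7767316,5.81086,0.135427,0.194493,6.14078
66.4529199,5.41371,0.13481,0.185178,5.7337
68.1724819,5.04222,0.134186,0.176294,5.3527
69.93654,4.69575,0.133554,0.167823,4.99712
71.7462455,4.37264,0.132914,0.159746,4.6653
73.6027797,4.07134,0.132266,0.152046,4.35565
75.5073543,3.79042,0.131611,0.144706,4.06674
77.4612125,3.52852,0.130949,0.137711,3.79718
79.4656294,3.28438,0.130278,0.131046,3.54571
81.5219134,3.05438,0.129601,0.124695,3.30867
83.6314067,2.83962,0.128916,0.118645,3.08718
85.795486,2.63994,0.128224,0.112882,2.88105
88.0155639,2.45429,0.127525,0.107393,2.68921
90.2930894,2.28168,0.126819,0.102166,2.51067
92.6295491,2.1212,0.126106,0.0971879,2.34449
95.0264679,1.97198,0.125386,0.0924485,2.18982
97.4854103,1.83326,0.12466,0.0879365,2.04585
100.007981,1.70427,0.123928,0.0836413,1.91184
102.595827,1.58436,0.123189,0.0795528,1.7871
105.250638,1.47286,0.122444,0.0756616,1.67097
107.974145,1.36921,0.121693,0.0719584,1.56286
110.768126,1.27284,0.120936,0.0684345,1.46221
113.634406,1.18324,0.120174,0.0650814,1.36849
116.574855,1.09994,0.119406,0.0618911,1.28124
119.591392,1.0225,0.118632,0.058856,1.19999
122.685986,0.9505,0.117854,0.0559687,1.12432
125.860657,0.883564,0.11707,0.0532223,1.05386
129.117477,0.821335,0.116282,0.05061,0.988227
132.458572,0.763483,0.115489,0.0481255,0.927098
135.886122,0.7097,0.114692,0.0457628,0.870154
139.402365,0.6597,0.11389,0.043516,0.817106
143.009596,0.613217,0.113085,0.0413797,0.767682
146.710169,0.570005,0.112276,0.0393484,0.721629
150.506499,0.529833,0.111463,0.0374172,0.678713
154.401065,0.492488,0.110646,0.0355814,0.638716
158.396408,0.457772,0.109827,0.0338363,0.601435
162.495136,0.425499,0.109004,0.0321776,0.566681
166.699924,0.395498,0.108179,0.0306011,0.534278
171.013517,0.367609,0.107351,0.0291029,0.504064
175.438731,0.341684,0.106521,0.0276793,0.475885
179.978453,0.317585,0.105689,0.0263266,0.4496
184.635646,0.295182,0.104854,0.0250414,0.425078
189.413351,0.274358,0.104018,0.0238206,0.402197
194.314686,0.255001,0.103181,0.0226609,0.380842
199.342849,0.237007,0.102342,0.0215596,0.360908
204.501124,0.220281,0.101502,0.0205137,0.342297
209.792876,0.204734,0.100661,0.0195206,0.324916
215.221559,0.190283,0.0998189,0.0185778,0.30868
220.790717,0.17685,0.0989766,0.017683,0.29351
226.503985,0.164364,0.098134,0.0168337,0.279332
232.365092,0.152759,0.0972913,0.0160278,0.266078
238.377862,0.141972,0.0964486,0.0152633,0.253684
244.546222,0.131945,0.0956061,0.0145382,0.24209
250.874197,0.122626,0.094764,0.0138506,0.231241
257.365917,0.113964,0.0939226,0.0131988,0.221085
264.025619,0.105913,0.0930819,0.012581,0.211576
270.85765,0.0984304,0.0922421,0.0119957,0.202668
277.86647,0.0914756,0.0914034,0.0114414,0.19432
285.056652,0.0850116,0.090566,0.0109166,0.186494
292.432891,0.0790038,0.0897299,0.0104198,0.179154
300,0.0734201,0.0888955,0.00994995,0.172266
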