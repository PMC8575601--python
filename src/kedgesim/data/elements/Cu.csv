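energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,mu_over_rho_cm2_g
4,334.78,0.180023,4.22183,339.182
4.10350558,312.271,0.179952,4.17614,316.627
4.20968951,291.253,0.179879,4.129,295.562
4.3186211,271.63,0.179804,4.08044,275.89
4.43037145,253.311,0.179728,4.03043,257.521
4.54501349,236.209,0.179649,3.979,240.368
4.66262206,220.246,0.179569,3.92615,224.352
4.78327391,205.337,0.179487,3.8719,209.388
4.90704779,191.401,0.179402,3.81627,195.397
5.0340245,178.4,0.179316,3.75929,182.338
5.16428691,166.27,0.179227,3.701,170.151
5.29792004,154.956,0.179137,3.64142,158.776
5.43501111,144.402,0.179044,3.58061,148.161
5.5756496,134.558,0.178948,3.51862,138.255
5.71992732,125.377,0.178851,3.45549,129.011
5.86793842,116.815,0.178751,3.3913,120.385
6.01977951,108.83,0.178649,3.32612,112.335
6.1755497,101.385,0.178544,3.26,104.823
6.33535067,94.4428,0.178436,3.19304,97.8143
6.4992867,87.9704,0.178326,3.12532,91.2741
6.66746482,81.9363,0.178214,3.05692,85.1714
6.83999477,76.311,0.178098,2.98795,79.4771
7.01698918,71.0673,0.17798,2.91849,74.1638
7.19856356,66.1796,0.177859,2.84865,69.2061
7.38483644,61.624,0.177735,2.77852,64.5802
7.57592938,57.3781,0.177608,2.70823,60.2639
7.77196713,53.4212,0.177478,2.63786,56.2365
7.97307762,49.7338,0.177345,2.56754,52.4787
8.17939213,46.2978,0.177209,2.49736,48.9724
8.39104531,43.0963,0.17707,2.42744,45.7008
8.60817531,40.1134,0.176927,2.35788,42.6482
8.83092386,37.3343,0.176781,2.28879,39.7999
8.97889098,35.621,0.176684,2.24415,38.0418
8.97890893,287.831,0.176684,2.24414,290.252
9.05943633,280.257,0.176631,2.22027,282.654
9.29386189,259.961,0.176478,2.1524,262.29
9.53435353,242.385,0.176321,2.0853,244.647
9.78106823,226.963,0.176161,2.01905,229.158
10.034167,212.474,0.175997,1.95372,214.604
10.2938151,198.867,0.175829,1.88941,200.932
10.5601819,186.09,0.175657,1.82618,188.092
10.8334414,174.095,0.175481,1.7641,176.035
11.1137718,162.837,0.175301,1.70322,164.716
11.4013561,152.273,0.175117,1.64361,154.092
11.6963821,142.357,0.174929,1.5853,144.117
11.9990423,132.999,0.174736,1.52834,134.702
12.3095343,124.235,0.174539,1.47276,125.882
12.6280607,116.03,0.174338,1.41858,117.623
12.9548293,108.348,0.174132,1.36583,109.888
13.2900536,101.159,0.173921,1.31451,102.647
13.6339523,94.4306,0.173705,1.26465,95.8689
13.9867498,88.1351,0.173485,1.21623,89.5248
14.3486765,82.2456,0.17326,1.16926,83.5881
14.7199685,76.7368,0.17303,1.12372,78.0336
15.1008683,71.585,0.172794,1.07962,72.8374
15.4916243,66.7678,0.172553,1.03693,67.9773
15.8924917,62.2642,0.172307,0.995639,63.4322
16.3037321,58.0547,0.172056,0.955721,59.1825
16.7256139,54.1206,0.171799,0.917154,55.2095
17.1584125,50.4445,0.171537,0.879912,51.4959
17.6024103,47.0101,0.171269,0.843967,48.0253
18.0578973,43.7992,0.170995,0.809292,44.7794
18.5251706,40.7928,0.170715,0.775856,41.7394
19.0045352,37.9877,0.170429,0.743627,38.9018
19.496304,35.3708,0.170138,0.712575,36.2535
20.0007981,32.9297,0.16984,0.682666,33.7822
20.5183467,30.653,0.169535,0.653871,31.4764
21.0492875,28.5298,0.169225,0.626155,29.3251
21.5939672,26.55,0.168908,0.599487,27.3184
22.1527412,24.7043,0.168584,0.573836,25.4468
22.7259743,22.9838,0.168254,0.549169,23.7012
23.3140406,21.3802,0.167917,0.525457,22.0736
23.9173239,19.8857,0.167573,0.502668,20.5559
24.5362181,18.4931,0.167222,0.480772,19.1411
25.1711269,17.1958,0.166864,0.459741,17.8224
25.822465,15.9873,0.166499,0.439545,16.5933
26.4906573,14.8617,0.166127,0.420157,15.448
27.17614,13.8111,0.165747,0.401549,14.3784
27.8793605,12.8324,0.16536,0.383694,13.3815
28.6007779,11.9218,0.164966,0.366567,12.4534
29.3408629,11.0747,0.164564,0.350141,11.5894
30.1000987,10.2867,0.164154,0.334393,10.7852
30.8789807,9.55375,0.163737,0.319298,10.0368
31.6780174,8.8721,0.163311,0.304833,9.34024
32.4977303,8.2382,0.162878,0.290975,8.69206
33.3386544,7.64879,0.162437,0.277701,8.08893
34.2013386,7.10079,0.161988,0.264991,7.52777
35.086346,6.59135,0.16153,0.252824,7.0057
35.9942541,6.1178,0.161065,0.241178,6.52005
36.9256557,5.67767,0.160591,0.230034,6.06829
37.8811585,5.26863,0.160109,0.219374,5.64811
38.8613864,4.88853,0.159618,0.209179,5.25733
39.866979,4.53249,0.159119,0.19943,4.89104
40.8985927,4.202,0.158611,0.19011,4.55072
41.9569008,3.89536,0.158095,0.181202,4.23466
43.0425941,3.61089,0.157571,0.17269,3.94115
44.1563813,3.34699,0.157037,0.164558,3.66858
45.2989893,3.10219,0.156495,0.156791,3.41547
46.4711638,2.87511,0.155944,0.149373,3.18043
47.67367,2.6645,0.155385,0.142291,2.96217
48.9072928,2.46916,0.154816,0.13553,2.75951
50.1728372,2.288,0.154239,0.129077,2.57132
51.4711294,2.12001,0.153653,0.122919,2.39658
52.8030166,1.96422,0.153059,0.117045,2.23433
54.1693684,1.81977,0.152455,0.11144,2.08367
55.5710763,1.68584,0.151843,0.106095,1.94378
57.0090555,1.56167,0.151221,0.100998,1.81389
58.4842443,1.44656,0.150591,0.0961382,1.69328
59.9976057,1.33984,0.149953,0.0915051,1.5813
61.5501275,1.24092,0.149305,0.0870888,1.47731
63.1428229,1.14923,0.148649,0.0828799,1.38076
64.7767316,1.06425,0.147984,0.078869,1.2911
66.4529199,0.985488,0.14731,0.0750475,1.20785
68.1724819,0.912499,0.146628,0.0714068,1.13053
69.93654,0.844861,0.145937,0.0679388,1.05874
71.7462455,0.782188,0.145238,0.0646357,0.992061
73.6027797,0.724117,0.14453,0.0614899,0.930137
75.5073543,0.670315,0.143814,0.0584944,0.872623
77.4612125,0.62047,0.14309,0.0556423,0.819203
79.4656294,0.574295,0.142358,0.0529269,0.76958
81.5219134,0.531522,0.141617,0.0503419,0.723482
83.6314067,0.491903,0.140869,0.0478814,0.680654
85.795486,0.455208,0.140113,0.0455396,0.640861
88.0155639,0.421223,0.139349,0.0433109,0.603883
90.2930894,0.38975,0.138578,0.04119,0.569518
92.6295491,0.360605,0.137799,0.0391719,0.537576
95.0264679,0.333618,0.137012,0.0372518,0.507883
97.4854103,0.308631,0.136219,0.0354251,0.480275
100.007981,0.285496,0.135418,0.0336873,0.454602
102.595827,0.264079,0.134611,0.0320343,0.430724
105.250638,0.244252,0.133797,0.0304621,0.408511
107.974145,0.225899,0.132976,0.0289667,0.387842
110.768126,0.208912,0.132149,0.0275446,0.368606
113.634406,0.193189,0.131316,0.0261923,0.350697
116.574855,0.178638,0.130477,0.0249064,0.334021
119.591392,0.165172,0.129632,0.0236837,0.318488
122.685986,0.152711,0.128781,0.0225213,0.304014
125.860657,0.141181,0.127925,0.0214163,0.290522
129.117477,0.130513,0.127064,0.0203658,0.277943
132.458572,0.120643,0.126197,0.0193674,0.266208
135.886122,0.111512,0.125326,0.0184185,0.255257
139.402365,0.103066,0.12445,0.0175166,0.245033
143.009596,0.0952528,0.12357,0.0166597,0.235483
146.710169,0.0880263,0.122686,0.0158454,0.226558
150.506499,0.0813427,0.121798,0.0150718,0.218212
154.401065,0.0751616,0.120906,0.0143368,0.210404
158.396408,0.0694456,0.12001,0.0136387,0.203095
162.495136,0.0641601,0.119111,0.0129757,0.196247
166.699924,0.059273,0.11821,0.0123461,0.189829
171.013517,0.0547546,0.117305,0.0117482,0.183808
175.438731,0.0505772,0.116398,0.0111807,0.178156
179.978453,0.0467155,0.115488,0.0106419,0.172846
184.635646,0.0431458,0.114577,0.0101306,0.167853
189.413351,0.0398462,0.113663,0.00964538,0.163155
194.314686,0.0367966,0.112748,0.00918508,0.158729
199.342849,0.0339781,0.111831,0.00874848,0.154557
204.501124,0.0313735,0.110913,0.00833447,0.150621
209.792876,0.0289666,0.109994,0.00794197,0.146902
215.221559,0.0267426,0.109074,0.00756998,0.143387
220.790717,0.0246877,0.108154,0.00721752,0.140059
226.503985,0.0227892,0.107233,0.00688368,0.136906
232.365092,0.0210354,0.106312,0.00656758,0.133915
238.377862,0.0194152,0.105391,0.00626842,0.131075
244.546222,0.0179187,0.104471,0.00598539,0.128375
250.874197,0.0165364,0.103551,0.00571774,0.125805
257.365917,0.0152597,0.102631,0.00546478,0.123356
264.025619,0.0140807,0.101712,0.00522582,0.121019
270.85765,0.012992,0.100795,0.00500022,0.118787
277.86647,0.0119866,0.0998784,0.00478737,0.116652
285.056652,0.0110583,0.0989633,0.00458668,0.114608
292.432891,0.0102013,0.0980498,0.00439761,0.112649
300,0.00941,0.0971379,0.00421961,0.110768
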