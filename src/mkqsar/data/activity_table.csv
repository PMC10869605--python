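compound_id,r1,r2,r3,ring,measured_lg_ic50,hm,gep,rf,svr_single,svr_double,svr_triple,is_test
1,H,H,H,figure,1.0086,1.0480,1.4606,1.0899,1.2200,1.0728,1.2200,1
2,H,F,H,figure,0.7782,1.0871,0.9972,0.8096,0.9442,0.9517,0.9373,0
3,H,H,F,figure,1.3802,1.2053,1.0629,1.0685,1.3561,1.3675,1.3563,0
4,H,F,H,figure,0.6902,0.7277,0.6955,0.6945,0.6659,0.6774,0.6659,0
5,H,H,H,figure,0.7993,0.7922,0.9886,0.8630,0.8140,0.7881,0.8140,1
6,H,F,H,figure,0.7160,0.9350,0.8954,0.6831,0.8124,0.8201,0.7962,0
7,F,H,H,figure,0.9590,1.0478,1.0962,0.9185,0.9346,0.9459,0.9349,0
8,H,F,H,figure,1.4594,1.1364,1.0550,0.9721,1.0666,1.0749,1.0782,0
9,H,F,H,figure,0.5185,0.7771,0.7436,0.6377,0.6878,0.7119,0.6878,1
10,H,F,H,figure,0.7634,0.6953,1.1288,0.8384,0.7878,0.7760,0.7875,0
11,H,F,H,figure,1.4082,1.1383,1.0468,0.9584,1.1978,1.2552,1.2064,0
12,H,H,H,figure,0.8261,0.8217,1.0543,0.8586,0.9331,0.9033,0.9331,1
13,H,F,H,figure,0.8129,0.6934,0.7544,0.8265,0.6387,0.6627,0.6387,1
14,H,F,H,figure,1.1173,1.0121,0.9203,1.0431,1.1414,1.1301,1.0937,0
15,H,F,H,figure,1.0569,1.1801,1.1249,0.9004,1.0812,1.0693,1.0805,0
16,H,F,H,figure,1.0253,0.7540,0.8502,1.0659,1.0016,1.0128,1.0013,0
17,H,H,CH_3,,1.1987,1.0851,0.9446,1.2289,1.2230,1.2039,1.2223,0
18,H,CH3,CH_3,,1.1818,0.9383,0.8455,0.9208,1.1011,1.1694,1.1581,0
19,H,H,CH_2CH_2N(CH_3)_2,,1.1761,1.1981,1.2457,0.9703,1.2482,1.2250,1.2478,0
20,H,H,CH_2CH_2N(CH_2CH_3)_2,,1.1931,0.7624,0.7404,1.0806,0.7965,0.8780,0.8462,0
21,H,H,CH_2CH_2NBn_2,,2.9031,2.7748,2.2265,1.8054,2.3226,2.5306,2.3226,1
22,H,H,figure,,1.0212,0.9255,0.7426,0.9875,0.8878,1.0086,0.9971,0
23,H,H,figure,,1.0128,1.0061,1.1865,1.0120,0.9883,1.0005,0.9891,0
24,H,H,figure,,2.5441,2.3479,2.4532,2.4998,2.5196,2.3828,2.4649,0
25,H,CH3,CH_2CH_2N(CH_3)_2,,0.7404,0.8768,0.8938,0.8139,0.8862,0.9145,0.8930,0
26,F,CH3,CH_2CH_3N(CH_3)_2,,0.8129,1.0090,0.7815,0.7898,0.8372,0.8260,0.8372,0
27,H,CH3,CH_2CH_2N(CH_2CH_3)_2,,0.5185,0.6547,0.8305,0.8301,0.7285,0.6997,0.6425,0
28,H,CH3,CH_2CH_2NBn_2,,2.7076,2.8163,2.6808,2.3985,2.6835,2.6951,2.6842,0
29,H,CH3,figure,,0.8195,0.9021,0.8349,0.8195,0.7954,0.8086,0.7961,0
30,H,CH_3,figure,,0.4624,0.7450,0.8832,0.7651,0.6989,0.7135,0.6598,0
31,H,CH_3,figure,,2.2788,2.0614,2.1938,2.2788,2.2725,2.2663,2.2547,0
32,H,CH_3,figure,,1.3617,0.9713,1.0690,1.2968,1.3373,1.3487,1.3377,0
33,H,CH_3,figure,,1.4314,1.8920,1.0923,1.4314,1.5439,1.4441,1.4552,0
34,H,CH_3,CH_2CH_2 NHCH_3,,0.8451,1.0300,0.9006,0.8653,0.9870,1.0752,0.9870,1
35,H,H,,,1.1959,1.0914,1.1661,1.0889,1.1718,1.1834,1.1725,0
36,F,H,,,0.9294,0.7868,0.7288,1.0242,0.8037,0.9158,0.9056,0
37,F,CH_3,,,0.7559,1.0302,0.8291,0.6576,0.7136,0.7432,0.7318,0
38,F,CH_2CH_3,,,0.6628,0.7414,0.7206,0.6732,0.6867,0.7006,0.6943,0
39,F,CH_2CH_2CH_3,,,0.6532,0.9517,0.8863,0.6829,0.7932,0.7153,0.6835,0
40,H,CH(CH_3)_2,,,0.8513,0.9240,0.8963,0.8273,0.7244,0.7829,0.7244,1
41,F,CH(CH_3)_2,,,0.7076,1.0675,0.8806,0.7076,0.8558,0.8060,0.7999,0
42,F,CH_2 CH_2CH_2CH_3,,,0.5798,0.7356,0.8124,0.6091,0.7469,0.7113,0.7469,1
43,H,figure,,,0.5185,0.7679,0.7753,0.5479,0.5685,0.5860,0.5474,0
44,F,figure,,,0.3617,0.7052,0.6998,0.3878,0.6200,0.5915,0.5470,0
45,F,figure,,,0.9912,0.8559,0.9505,0.6812,0.9069,0.8375,0.9069,1
46,F,figure,,,1.4487,1.4786,1.5203,1.3075,1.4730,1.4614,1.4723,0
47,F,figure,,,0.6721,1.1065,0.9807,0.6588,0.6962,0.8079,0.6962,0
48,F,figure,,,1.2529,0.9978,1.0747,1.0754,1.2285,1.2399,1.2286,0
49,F,figure,,,0.8633,0.6836,0.7265,0.8156,0.8391,0.8508,0.8392,0
50,F,figure,,,0.9031,0.6838,0.7577,0.7876,0.9277,0.9159,0.9267,0
51,F,figure,,,0.9956,0.5959,0.7650,0.9328,0.9403,0.9290,0.9403,1
52,H,figure,,,0.8573,0.7521,0.7321,0.8573,0.8336,0.8448,0.8334,0
53,F,figure,,,1.0792,0.7365,0.7139,0.8423,1.0121,0.9618,0.9450,0
54,F,figure,,,0.8195,1.0923,0.8548,0.5479,1.0716,1.0080,1.0716,1
55,H,,,figure,0.9138,0.9582,1.0044,0.9069,0.8895,0.9262,0.9379,0
56,F,,,figure,0.7076,0.9856,0.8237,0.7244,0.7324,0.7202,0.7316,0
57,F,,,figure,1.8633,1.3363,1.1642,0.8030,1.3451,1.3750,1.4129,0
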