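age,sex,rate_all_cause,rate_mi,rate_stroke
19,male,0.00033559,1.342e-05,1.007e-05
20,male,0.00036537,1.461e-05,1.096e-05
21,male,0.00039778,1.591e-05,1.193e-05
22,male,0.00043307,1.732e-05,1.299e-05
23,male,0.00047149,1.886e-05,1.414e-05
24,male,0.00051332,2.053e-05,1.54e-05
25,male,0.00055886,2.235e-05,1.677e-05
26,male,0.00060844,2.434e-05,1.825e-05
27,male,0.00066242,2.65e-05,1.987e-05
28,male,0.00072119,2.885e-05,2.164e-05
29,male,0.00078517,3.141e-05,2.356e-05
30,male,0.00085483,3.419e-05,2.564e-05
31,male,0.00093067,3.723e-05,2.792e-05
32,male,0.00101323,4.053e-05,3.04e-05
33,male,0.00110313,4.413e-05,3.309e-05
34,male,0.00120099,4.804e-05,3.603e-05
35,male,0.00130754,5.23e-05,3.923e-05
36,male,0.00142354,5.694e-05,4.271e-05
37,male,0.00154983,6.199e-05,4.649e-05
38,male,0.00168733,6.749e-05,5.062e-05
39,male,0.00183702,7.348e-05,5.511e-05
40,male,0.002,8e-05,6e-05
41,male,0.00217743,8.71e-05,6.532e-05
42,male,0.00237061,9.482e-05,7.112e-05
43,male,0.00258092,0.00010324,7.743e-05
44,male,0.0028099,0.0001124,8.43e-05
45,male,0.00305918,0.00012237,9.178e-05
46,male,0.00333058,0.00013322,9.992e-05
47,male,0.00362606,0.00014504,0.00010878
48,male,0.00394776,0.00015791,0.00011843
49,male,0.00429799,0.00017192,0.00012894
50,male,0.00467929,0.00018717,0.00014038
51,male,0.00509443,0.00020378,0.00015283
52,male,0.00554639,0.00022186,0.00016639
53,male,0.00603845,0.00024154,0.00018115
54,male,0.00657416,0.00026297,0.00019722
55,male,0.0071574,0.0002863,0.00021472
56,male,0.00779239,0.0003117,0.00023377
57,male,0.0084837,0.00033935,0.00025451
58,male,0.00923635,0.00036945,0.00027709
59,male,0.01005578,0.00040223,0.00030167
60,male,0.01094789,0.00043792,0.00032844
61,male,0.01191916,0.00047677,0.00035757
62,male,0.01297659,0.00051906,0.0003893
63,male,0.01412784,0.00056511,0.00042384
64,male,0.01538122,0.00061525,0.00046144
65,male,0.01674579,0.00066983,0.00050237
66,male,0.01823143,0.00072926,0.00054694
67,male,0.01984887,0.00079395,0.00059547
68,male,0.02160981,0.00086439,0.00064829
69,male,0.02352696,0.00094108,0.00070581
70,male,0.02561421,0.00102457,0.00076843
71,male,0.02788662,0.00111546,0.0008366
72,male,0.03036064,0.00121443,0.00091082
73,male,0.03305415,0.00132217,0.00099162
74,male,0.03598662,0.00143946,0.0010796
75,male,0.03917925,0.00156717,0.00117538
76,male,0.04265511,0.0017062,0.00127965
77,male,0.04643935,0.00185757,0.00139318
78,male,0.05055931,0.00202237,0.00151678
79,male,0.05504479,0.00220179,0.00165134
80,male,0.0599282,0.00239713,0.00179785
81,male,0.06524485,0.00260979,0.00195735
82,male,0.07103319,0.00284133,0.002131
83,male,0.07733504,0.0030934,0.00232005
84,male,0.08419598,0.00336784,0.00252588
85,male,0.0916656,0.00366662,0.00274997
19,female,0.00018458,7.38e-06,5.54e-06
20,female,0.00020095,8.04e-06,6.03e-06
21,female,0.00021878,8.75e-06,6.56e-06
22,female,0.00023819,9.53e-06,7.15e-06
23,female,0.00025932,1.037e-05,7.78e-06
24,female,0.00028233,1.129e-05,8.47e-06
25,female,0.00030737,1.229e-05,9.22e-06
26,female,0.00033464,1.339e-05,1.004e-05
27,female,0.00036433,1.457e-05,1.093e-05
28,female,0.00039665,1.587e-05,1.19e-05
29,female,0.00043184,1.727e-05,1.296e-05
30,female,0.00047016,1.881e-05,1.41e-05
31,female,0.00051187,2.047e-05,1.536e-05
32,female,0.00055728,2.229e-05,1.672e-05
33,female,0.00060672,2.427e-05,1.82e-05
34,female,0.00066055,2.642e-05,1.982e-05
35,female,0.00071915,2.877e-05,2.157e-05
36,female,0.00078295,3.132e-05,2.349e-05
37,female,0.00085241,3.41e-05,2.557e-05
38,female,0.00092803,3.712e-05,2.784e-05
39,female,0.00101036,4.041e-05,3.031e-05
40,female,0.0011,4.4e-05,3.3e-05
41,female,0.00119759,4.79e-05,3.593e-05
42,female,0.00130384,5.215e-05,3.912e-05
43,female,0.00141951,5.678e-05,4.259e-05
44,female,0.00154544,6.182e-05,4.636e-05
45,female,0.00168255,6.73e-05,5.048e-05
46,female,0.00183182,7.327e-05,5.495e-05
47,female,0.00199433,7.977e-05,5.983e-05
48,female,0.00217127,8.685e-05,6.514e-05
49,female,0.00236389,9.456e-05,7.092e-05
50,female,0.00257361,0.00010294,7.721e-05
51,female,0.00280193,0.00011208,8.406e-05
52,female,0.00305051,0.00012202,9.152e-05
53,female,0.00332115,0.00013285,9.963e-05
54,female,0.00361579,0.00014463,0.00010847
55,female,0.00393657,0.00015746,0.0001181
56,female,0.00428581,0.00017143,0.00012857
57,female,0.00466604,0.00018664,0.00013998
58,female,0.00507999,0.0002032,0.0001524
59,female,0.00553068,0.00022123,0.00016592
60,female,0.00602134,0.00024085,0.00018064
61,female,0.00655554,0.00026222,0.00019667
62,female,0.00713713,0.00028549,0.00021411
63,female,0.00777031,0.00031081,0.00023311
64,female,0.00845967,0.00033839,0.00025379
65,female,0.00921019,0.00036841,0.00027631
66,female,0.01002729,0.00040109,0.00030082
67,female,0.01091688,0.00043668,0.00032751
68,female,0.01188539,0.00047542,0.00035656
69,female,0.01293983,0.00051759,0.00038819
70,female,0.01408781,0.00056351,0.00042263
71,female,0.01533764,0.00061351,0.00046013
72,female,0.01669835,0.00066793,0.00050095
73,female,0.01817978,0.00072719,0.00054539
74,female,0.01979264,0.00079171,0.00059378
75,female,0.02154859,0.00086194,0.00064646
76,female,0.02346031,0.00093841,0.00070381
77,female,0.02554164,0.00102167,0.00076625
78,female,0.02780762,0.0011123,0.00083423
79,female,0.03027463,0.00121099,0.00090824
80,female,0.03296051,0.00131842,0.00098882
81,female,0.03588467,0.00143539,0.00107654
82,female,0.03906825,0.00156273,0.00117205
83,female,0.04253427,0.00170137,0.00127603
84,female,0.04630779,0.00185231,0.00138923
85,female,0.05041608,0.00201664,0.00151248
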