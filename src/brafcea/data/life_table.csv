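# Synthetic all-cause life table (annual death probability by age, sex).
# Gompertz-Makeham stand-in for published US life tables; see module docs.
age,male,female
26,0.001550,0.000789
27,0.001613,0.000817
28,0.001682,0.000848
29,0.001756,0.000882
30,0.001837,0.000919
31,0.001924,0.000960
32,0.002019,0.001004
33,0.002122,0.001053
34,0.002234,0.001107
35,0.002355,0.001166
36,0.002487,0.001231
37,0.002629,0.001302
38,0.002784,0.001381
39,0.002951,0.001466
40,0.003133,0.001560
41,0.003330,0.001664
42,0.003544,0.001777
43,0.003775,0.001901
44,0.004027,0.002038
45,0.004299,0.002187
46,0.004595,0.002352
47,0.004916,0.002532
48,0.005263,0.002730
49,0.005640,0.002947
50,0.006049,0.003185
51,0.006493,0.003446
52,0.006974,0.003733
53,0.007495,0.004048
54,0.008061,0.004393
55,0.008674,0.004772
56,0.009340,0.005188
57,0.010061,0.005644
58,0.010843,0.006145
59,0.011692,0.006695
60,0.012612,0.007298
61,0.013610,0.007960
62,0.014692,0.008686
63,0.015865,0.009483
64,0.017138,0.010357
65,0.018518,0.011317
66,0.020015,0.012370
67,0.021639,0.013526
68,0.023399,0.014794
69,0.025308,0.016185
70,0.027379,0.017712
71,0.029624,0.019388
72,0.032059,0.021227
73,0.034700,0.023244
74,0.037563,0.025459
75,0.040669,0.027888
76,0.044037,0.030555
77,0.047690,0.033481
78,0.051651,0.036691
79,0.055947,0.040215
80,0.060606,0.044081
81,0.065658,0.048324
82,0.071137,0.052979
83,0.077080,0.058088
84,0.083524,0.063695
85,0.090512,0.069847
86,0.098091,0.076598
87,0.106310,0.084006
88,0.115223,0.092136
89,0.124890,0.101056
90,0.135373,0.110846
91,0.146741,0.121588
92,0.159070,0.133376
93,0.172441,0.146312
94,0.186941,0.160507
95,0.202666,0.176084
96,0.219720,0.193178
97,0.238214,0.211935
98,0.258270,0.232519
99,0.280021,0.255106
100,0.303610,0.279893
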