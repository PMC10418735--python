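compound_id,milogP,AlogPs,AClogP,ALOGP,MLOGP,XLOGP2,XLOGP3
1,0.75,1.01,0.85,1.82,1.20,0.83,1.35
2,1.25,1.86,1.31,2.34,1.54,1.18,1.88
3,1.81,2.37,1.78,2.80,1.85,1.75,2.23
4,1.50,1.53,1.65,2.66,1.85,1.48,2.31
5,1.20,1.39,1.28,2.02,1.54,1.03,1.54
6,1.97,2.26,2.18,3.05,2.46,2.02,2.64
7,2.78,2.82,2.88,3.80,3.13,2.82,3.33
8,2.37,2.54,1.99,3.15,2.45,1.97,2.55
9,1.12,1.88,1.36,2.24,1.85,1.05,1.65
10,1.40,1.35,1.00,2.02,1.54,1.24,1.53
11,1.77,2.33,1.46,2.55,1.85,1.60,2.06
12,2.33,2.89,1.93,3.00,2.16,2.17,2.42
13,2.01,2.06,1.80,2.87,2.16,1.90,2.50
14,1.71,0.85,1.43,2.23,1.85,1.44,1.72
15,2.48,2.52,2.34,3.26,2.73,2.44,2.83
16,3.29,3.59,3.04,4.01,3.39,3.24,3.52
17,2.88,3.12,2.14,3.36,2.73,3.39,2.73
18,1.63,2.30,1.51,2.45,2.16,1.46,1.83
19,3.00,3.00,2.03,3.23,3.27,2.82,3.22
20,3.51,3.52,2.49,3.76,3.52,3.18,3.75
21,4.07,3.91,2.95,4.21,3.77,3.75,4.11
22,3.75,3.52,2.83,4.08,3.77,3.48,4.19
23,3.45,3.52,2.46,3.44,3.52,3.02,3.14
24,4.22,4.09,3.37,4.47,4.21,4.02,4.52
25,5.03,4.93,4.06,5.22,4.82,4.82,5.21
26,4.62,4.34,3.17,4.57,4.25,3.97,4.42
27,3.37,3.47,2.54,3.66,3.77,3.04,3.52
28,2.64,2.74,1.46,2.86,3.00,2.53,2.82
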