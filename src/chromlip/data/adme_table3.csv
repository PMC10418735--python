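compound_id,log_s,caco2_log_papp,hia_pct,vdss_log,bbb_log_bb,fu
1,-1.477,1.393,95.751,-0.102,-0.235,0.606
2,-2.014,1.484,93.679,-0.074,-0.191,0.516
3,-2.459,1.483,92.838,-0.03,0.055,0.466
4,-2.198,1.113,94.017,-0.098,0.05,0.472
5,-1.831,1.395,94.12,-0.079,-0.219,0.577
6,-3.402,1.424,93.276,0.147,0.123,0.201
7,-4.349,1.227,91.821,0.133,0.078,0.184
8,-3.206,1.08,93.185,0.032,0.063,0.341
9,-2.386,1.106,94.229,0.012,-0.173,0.47
10,-2.124,1.495,93.305,-0.137,-0.208,0.49
11,-2.519,1.495,92.685,-0.097,0.109,0.442
12,-2.946,1.494,91.845,-0.057,0.097,0.394
13,-2.976,1.51,92.211,-0.094,0.107,0.375
14,-2.311,1.407,93.34,-0.077,0.173,0.518
15,-3.968,1.437,92.51,0.144,0.151,0.145
16,-4.893,1.239,91.055,0.129,0.106,0.128
17,-3.673,1.093,92.419,0.006,0.09,0.282
18,-2.866,1.118,93.462,-0.001,0.092,0.409
19,-4.228,1.457,93.571,0.42,0.233,0.326
20,-4.43,1.456,92.938,0.435,0.219,0.281
21,-4.635,1.455,92.091,0.448,0.208,0.234
22,-4.693,1.471,92.45,0.404,0.235,0.218
23,-4.477,1.459,93.182,0.437,0.246,0.297
24,-4.889,1.614,92.226,0.677,0.226,0.079
25,-5.394,1.154,90.777,0.641,0.197,0.033
26,-5.026,1.468,91.916,0.36,0.218,0.118
27,-4.753,1.457,92.783,0.429,0.169,0.205
28,-3.943,1.445,93.949,0.421,0.222,0.376
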