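compound_id,cyp2d6,cyp3a4,cyp1a2,cyp2c19,cyp2c9,cl_tot
1,No,No,No,No,No,0.164
2,No,No,No,No,No,0.203
3,No,No,No,No,No,0.227
4,No,No,No,No,No,0.187
5,No,No,No,No,No,0.091
6,No,No,Yes,No,No,0.023
7,No,No,Yes,Yes,No,-0.129
8,No,No,No,No,No,0.043
9,No,No,No,No,No,-0.043
10,No,No,No,No,No,0.061
11,No,No,No,No,No,0.1
12,No,No,No,No,No,0.123
13,No,No,No,No,No,0.083
14,No,No,No,No,No,-0.013
15,No,No,Yes,Yes,No,-0.083
16,No,No,Yes,Yes,Yes,-0.235
17,No,No,No,No,No,-0.063
18,No,No,No,No,No,-0.149
19,No,No,No,No,No,-0.302
20,No,No,No,Yes,No,-0.264
21,No,No,No,Yes,No,-0.239
22,No,No,No,Yes,No,-0.283
23,No,No,No,No,No,-0.381
24,Yes,No,No,Yes,No,-0.422
25,Yes,No,No,Yes,No,-0.575
26,No,No,No,Yes,No,-0.403
27,No,No,No,No,No,-0.488
28,No,No,No,No,No,-0.24
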