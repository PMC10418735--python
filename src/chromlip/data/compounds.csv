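compound_id,series,r1,r2,spiro
1,isopropylamino,H,CH3,
2,isopropylamino,H,C2H5,
3,isopropylamino,H,C3H7,
4,isopropylamino,H,CH(CH3)2,
5,isopropylamino,CH3,CH3,
6,isopropylamino,H,C6H5,
7,isopropylamino,H,C6H4-p-Br,
8,isopropylamino,,,C5H10
9,isopropylamino,,,C3H6
10,tert-butylamino,H,CH3,
11,tert-butylamino,H,C2H5,
12,tert-butylamino,H,C3H7,
13,tert-butylamino,H,CH(CH3)2,
14,tert-butylamino,CH3,CH3,
15,tert-butylamino,H,C6H5,
16,tert-butylamino,H,C6H4-p-Br,
17,tert-butylamino,,,C5H10
18,tert-butylamino,,,C3H6
19,adamantylamino,H,CH3,
20,adamantylamino,H,C2H5,
21,adamantylamino,H,C3H7,
22,adamantylamino,H,CH(CH3)2,
23,adamantylamino,CH3,CH3,
24,adamantylamino,H,C6H5,
25,adamantylamino,H,C6H4-p-Br,
26,adamantylamino,,,C5H10
27,adamantylamino,,,C3H6
28,adamantylamino,H,H,
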