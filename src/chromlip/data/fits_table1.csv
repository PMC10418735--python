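compound_id,technique,intercept,slope,phi0,abs_correlation
1,RP-HPLC,1.35,-2.975,0.454,0.9953
2,RP-HPLC,1.86,-3.254,0.571,0.9885
3,RP-HPLC,2.28,-3.494,0.652,0.9988
4,RP-HPLC,2.28,-3.603,0.633,0.9942
5,RP-HPLC,1.94,-3.400,0.571,0.9855
6,RP-HPLC,2.84,-4.3069,0.659,0.9767
7,RP-HPLC,3.22,-4.422,0.728,0.9956
8,RP-HPLC,2.97,-4.170,0.712,0.9652
9,RP-HPLC,1.79,-2.890,0.619,0.9958
10,RP-HPLC,1.74,-3.122,0.557,0.9901
11,RP-HPLC,1.88,-3.073,0.612,0.9927
12,RP-HPLC,2.46,-3.606,0.682,0.9979
13,RP-HPLC,2.39,-3.585,0.667,0.9974
14,RP-HPLC,2.02,-3.320,0.608,0.9932
15,RP-HPLC,3.25,-4.449,0.730,0.9623
16,RP-HPLC,3.38,-4.537,0.745,0.9984
17,RP-HPLC,2.86,-3.904,0.732,0.9993
18,RP-HPLC,2.15,-3.297,0.652,0.9987
19,RP-HPLC,3.22,-4.099,0.786,0.9990
20,RP-HPLC,3.60,-4.437,0.811,0.9988
21,RP-HPLC,4.08,-4.859,0.840,0.9983
22,RP-HPLC,3.94,-4.744,0.830,0.9984
23,RP-HPLC,3.54,-4.392,0.806,0.9989
24,RP-HPLC,4.13,-5.024,0.822,0.9984
25,RP-HPLC,5.63,-5.578,1.009,0.9291
26,RP-HPLC,4.49,-5.192,0.865,0.9974
27,RP-HPLC,3.66,-4.383,0.835,0.9973
28,RP-HPLC,2.87,-3.783,0.759,0.9993
1,RP-TLC,0.94,-1.280,0.734,0.8623
2,RP-TLC,1.39,-2.075,0.668,0.9590
3,RP-TLC,1.63,-2.422,0.673,0.9627
4,RP-TLC,1.41,-2.127,0.663,0.9462
5,RP-TLC,1.20,-1.903,0.629,0.9367
6,RP-TLC,1.58,-2.049,0.771,0.9619
7,RP-TLC,2.85,-3.870,0.736,0.9689
8,RP-TLC,2.04,-2.877,0.709,0.9530
9,RP-TLC,1.37,-1.990,0.691,0.9789
10,RP-TLC,1.57,-2.393,0.658,0.9572
11,RP-TLC,1.59,-2.478,0.643,0.9686
12,RP-TLC,1.71,-2.426,0.703,0.9325
13,RP-TLC,1.46,-2.095,0.699,0.9075
14,RP-TLC,1.19,-1.826,0.652,0.9207
15,RP-TLC,3.17,-4.293,0.739,0.9371
16,RP-TLC,3.20,-4.131,0.774,0.9662
17,RP-TLC,1.89,-2.477,0.762,0.8269
18,RP-TLC,1.69,-2.476,0.683,0.8583
19,RP-TLC,2.55,-3.148,0.810,0.9107
20,RP-TLC,2.30,-2.678,0.860,0.9657
21,RP-TLC,2.33,-2.564,0.909,0.9001
22,RP-TLC,2.67,-3.175,0.872,0.8719
23,RP-TLC,2.11,-2.446,0.863,0.9127
24,RP-TLC,3.31,-4.203,0.787,0.9636
25,RP-TLC,3.56,-3.277,1.086,0.9226
26,RP-TLC,3.09,-3.520,0.879,0.9624
27,RP-TLC,2.56,-3.025,0.847,0.9797
28,RP-TLC,2.06,-2.482,0.832,0.9770
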