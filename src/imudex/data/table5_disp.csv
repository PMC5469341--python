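volunteer,sensor,e1,e2,e3
1,1,3.63,2.72,1.94
1,2,3.91,3.03,2.05
1,3,3.67,2.90,1.98
1,4,3.84,2.99,2.04
2,1,5.17,1.34,5.2
2,2,5.38,1.59,5.31
2,3,5.12,1.49,5.24
2,4,5.28,1.60,5.31
3,1,4.76,1.80,3.16
3,2,5.05,2.02,3.29
3,3,4.82,1.90,3.21
3,4,4.99,1.98,3.26
4,1,4.41,1.71,2.69
4,2,4.65,2.00,2.78
4,3,4.38,1.90,2.70
4,4,4.58,1.99,2.77
5,1,3.45,0.86,2.12
5,2,3.64,1.13,2.23
5,3,3.42,0.98,2.15
5,4,3.58,1.10,2.21
6,1,5.16,2.80,2.27
6,2,5.34,3.11,2.38
6,3,5.11,2.99,2.31
6,4,5.31,3.10,2.37
7,1,3.92,1.30,2.41
7,2,4.22,1.61,2.52
7,3,3.94,1.46,2.44
7,4,4.13,1.57,2.49
8,1,1.91,3.12,4.04
8,2,2.12,3.41,4.04
8,3,1.88,3.27,3.96
8,4,2.03,3.38,4.03
9,1,3.49,3.69,2.35
9,2,3.70,4.02,2.40
9,3,3.42,3.89,2.34
9,4,3.58,3.99,2.40
10,1,2.91,1.01,3.25
10,2,3.18,1.24,3.33
10,3,2.92,1.13,3.27
10,4,3.11,1.20,3.32
11,1,3.84,1.87,3.39
11,2,4.09,2.10,3.51
11,3,3.84,2.00,3.43
11,4,4.03,2.10,3.48
12,1,3.41,1.57,2.02
12,2,3.70,1.89,2.07
12,3,3.45,1.74,2.00
12,4,3.60,1.83,2.06
13,1,6.27,2.16,2.32
13,2,6.51,2.40,2.41
13,3,6.27,2.27,2.34
13,4,6.42,2.39,2.41
14,1,2.43,0.97,2.75
14,2,2.66,1.19,2.82
14,3,2.40,1.09,2.75
14,4,2.57,1.19,2.82
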