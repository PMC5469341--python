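volunteer,t_span,total_task1,t_ratio,errors
1,42.2,24.9,1.69,2
2,77.7,33.7,2.31,10
3,60.7,33.4,1.82,4
4,48,27.1,1.77,4
5,48.4,21.7,2.23,3
6,61.2,30.9,1.98,6
7,65.1,22.3,2.91,9
8,107.1,25,4.28,17
9,52.6,27.4,1.92,3
10,82.3,28.4,2.9,12
11,74.4,25,2.98,9
12,34.4,18.1,1.9,0
13,46.9,22.9,2.05,6
14,65.6,18.4,3.57,9
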