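volunteer,exercise1,exercise2,exercise3
1,19,11,32
2,19,11,51
3,20,10,35
4,19,10,33
5,19,11,31
6,19,11,47
7,19,10,56
8,19,10,71
9,19,10,32
10,21,10,60
11,20,10,56
12,19,10,25
13,20,10,37
14,19,10,51
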