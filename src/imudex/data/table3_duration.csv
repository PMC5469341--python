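volunteer,exercise1,exercise2,exercise3
1,44.0,21.6,43.1
2,33.8,16.3,78.6
3,50.9,29.5,60.7
4,23.6,10.8,47.7
5,40.9,19.5,49.4
6,37.6,19.2,60
7,42.3,29.9,65.1
8,25.4,15.3,106.3
9,46.1,24.5,51.8
10,36.7,17.8,77.9
11,43.1,20.0,74.4
12,28.4,17.3,34.9
13,23.5,13.5,48.3
14,29.5,15.8,66.6
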