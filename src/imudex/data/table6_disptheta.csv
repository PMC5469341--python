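volunteer,sensor,e1,e2,e3
1,1,1788,515,1387
1,2,2234,769,1565
1,3,1803,523,1415
1,4,2101,727,1568
2,1,2049,554,2578
2,2,2562,879,2854
2,3,2043,581,2584
2,4,2318,811,2787
3,1,1413,540,2080
3,2,1797,815,2272
3,3,1429,558,2052
3,4,1601,772,2237
4,1,1557,731,1432
4,2,1925,1104,1598
4,3,1561,735,1442
4,4,1798,1019,1545
5,1,1424,456,924
5,2,1715,708,1012
5,3,1402,478,916
5,4,1649,666,991
6,1,1585,532,1244
6,2,1996,795,1368
6,3,1575,534,1240
6,4,1812,731,1340
7,1,1530,499,1776
7,2,1897,782,1895
7,3,1541,523,1764
7,4,1734,720,1936
8,1,1601,666,1869
8,2,1980,1000,2032
8,3,1584,671,1854
8,4,1788,935,2031
9,1,1586,448,1184
9,2,1976,701,1297
9,3,1577,464,1198
9,4,1835,647,1299
10,1,1208,515,1415
10,2,1532,796,1552
10,3,1214,530,1426
10,4,1430,745,1559
11,1,1492,555,1499
11,2,1917,862,1714
11,3,1519,577,1520
11,4,1766,809,1671
12,1,1795,574,565
12,2,2215,892,612
12,3,1804,600,557
12,4,2085,832,602
13,1,1734,841,1103
13,2,2239,1288,1187
13,3,1754,870,1099
13,4,2015,1220,1188
14,1,1445,364,1401
14,2,1789,543,1547
14,3,1454,369,1418
14,4,1655,515,1519
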