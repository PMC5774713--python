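year,price_rubber,price_op
0,1270.9,78.7
1,1278.3,74.1
2,1324.2,80.1
3,1270.1,83.6
4,1249.1,79.0
5,1249.2,84.0
6,1173.2,84.8
7,1123.4,84.0
8,1133.7,74.7
9,1111.2,74.4
10,1111.6,73.3
11,1113.1,74.5
12,1109.7,63.6
13,1091.1,69.3
14,1139.8,66.1
15,1079.1,69.6
16,1054.6,74.4
17,1018.8,79.3
18,962.5,90.2
19,913.3,84.7
20,888.0,91.7
21,965.2,87.7
22,933.6,89.6
23,922.2,93.1
24,947.3,88.6
25,913.0,92.3
26,896.3,86.2
27,862.1,90.0
28,815.4,87.0
29,776.9,89.7
30,766.3,94.2
31,753.2,86.9
32,760.6,97.7
33,723.4,99.1
34,732.2,104.5
35,751.7,105.6
36,743.6,112.6
37,720.2,111.0
38,666.6,116.6
39,633.9,115.8
40,627.2,109.9
41,659.7,109.5
42,720.5,108.3
43,805.1,99.8
44,888.4,95.3
45,990.9,93.7
46,1080.4,94.4
47,1165.9,93.9
48,1236.3,78.6
49,1264.7,87.6
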