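batch,ratio_pct
1,14.58
2,10.11
3,10.01
4,19.37
5,4.39
6,14.62
7,10.89
8,6.55
9,3.01
10,13.18
11,12.34
12,3.86
13,26.49
14,18.0
15,17.39
16,8.68
17,13.17
18,10.06
19,18.16
20,18.35
21,6.95
22,14.07
23,4.05
24,15.74
25,20.82
26,19.76
27,12.18
28,6.5
29,11.44
30,20.98
31,16.0
32,18.64
33,19.07
34,13.07
35,11.62
36,11.24
37,27.33
38,5.14
39,10.62
40,11.36
41,16.55
42,12.48
43,7.64
44,13.02
45,16.05
46,6.23
47,6.53
48,17.48
49,20.13
50,13.19
51,20.62
52,20.18
53,13.7
54,18.64
55,13.68
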