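batch,analyte,esm_mgg,qams_mgg,re_pct
1,GV,2.896,,
1,GC,4.295,4.289,-0.14
1,C,1.048,1.047,-0.10
1,V,0.09829,0.09793,-0.37
1,GH,1.069,1.070,0.09
1,H,0.06459,0.06460,0.02
2,GV,0.8574,,
2,GC,2.646,2.642,-0.15
2,C,0.3916,0.3914,-0.05
2,V,0.04527,0.04511,-0.35
2,GH,0.2362,0.2364,0.08
2,H,0.1061,0.1061,0.00
3,GV,1.889,,
3,GC,3.783,3.778,-0.13
3,C,0.7479,0.7475,-0.05
3,V,0.06943,0.06918,-0.36
3,GH,0.9545,0.9553,0.08
3,H,0.1507,0.1507,0.00
4,GV,2.480,,
4,GC,2.885,2.881,-0.14
4,C,0.2100,0.2098,-0.10
4,V,0.05922,0.05901,-0.35
4,GH,0.2845,0.2847,0.07
4,H,0.020008,0.02009,0.05
5,GV,2.848,,
5,GC,3.510,3.505,-0.14
5,C,0.9254,0.9248,-0.06
5,V,0.08080,0.08051,-0.36
5,GH,0.7045,0.7051,0.09
5,H,0.06158,0.06159,0.02
6,GV,1.832,,
6,GC,2.019,2.016,-0.15
6,C,0.6268,0.6264,-0.06
6,V,0.05237,0.05219,-0.34
6,GH,0.2341,0.2343,0.09
6,H,0.02235,0.02236,0.04
7,GV,1.961,,
7,GC,2.241,2.239,-0.09
7,C,0.5400,0.5396,-0.07
7,V,0.05959,0.05937,-0.37
7,GH,0.2508,0.2510,0.08
7,H,0.07276,0.07278,0.03
8,GV,2.062,,
8,GC,2.249,2.246,-0.13
8,C,0.2459,0.2458,-0.04
8,V,0.06527,0.06503,-0.37
8,GH,0.2155,0.2157,0.09
8,H,0.0256,0.02565,0.00
9,GV,1.390,,
9,GC,4.122,4.123,0.02
9,C,0.3810,0.3809,-0.03
9,V,0.0398,0.03918,-0.51
9,GH,0.4580,0.4593,0.28
9,H,0.08772,0.08785,0.15
10,GV,3.961,,
10,GC,2.466,2.466,0.00
10,C,1.469,1.469,0.00
10,V,0.2263,0.2251,-0.53
10,GH,1.264,1.267,0.24
10,H,0.3047,0.3051,0.13
11,GV,2.004,,
11,GC,3.054,3.054,0.00
11,C,1.491,1.491,0.00
11,V,0.1301,0.1294,-0.54
11,GH,0.7997,0.8018,0.26
11,H,0.1760,0.1763,0.17
12,GV,2.519,,
12,GC,2.363,2.363,0.00
12,C,1.029,1.030,0.10
12,V,0.08996,0.08953,-0.48
12,GH,0.6982,0.6997,0.21
12,H,0.06253,0.06263,0.16
13,GV,2.848,,
13,GC,4.417,4.416,-0.02
13,C,1.754,1.756,0.11
13,V,0.1763,0.1754,-0.51
13,GH,0.9507,0.9528,0.22
13,H,0.1461,0.1463,0.14
14,GV,2.233,,
14,GC,4.983,4.983,0.00
14,C,0.799,0.800,0.09
14,V,0.07737,0.07700,-0.48
14,GH,0.8065,0.8082,0.21
14,H,0.07475,0.07487,0.16
15,GV,4.038,,
15,GC,3.972,3.973,0.03
15,C,1.239,1.238,-0.08
15,V,0.1380,0.1372,-0.58
15,GH,0.6367,0.6384,0.27
15,H,0.05454,0.05462,0.15
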