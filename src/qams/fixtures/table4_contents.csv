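batch,GC,C,GV,V,GH,H,total
1,1.31700,0.42750,1.26100,0.02920,0.29460,0.03354,3.36300
2,2.41800,0.49760,2.38200,0.04779,0.36590,0.03554,5.74700
3,2.65100,0.54580,2.69800,0.06159,0.37810,0.02972,6.36400
4,1.33700,0.67920,1.65400,0.04434,0.28590,0.06364,4.06400
5,2.68900,0.21970,2.87600,0.03020,0.31120,0.01964,6.14600
6,4.57300,1.10700,1.95500,0.03020,0.58870,0.08134,8.33500
7,1.72900,0.40010,1.83500,0.03092,0.16750,0.02509,4.18800
8,2.56400,0.39440,3.71800,0.04341,0.27230,0.02125,7.01300
9,2.43000,0.10140,2.25500,0.03667,0.24960,0.01529,5.08800
10,2.25800,0.67320,2.21600,0.00000,0.34630,0.05838,5.55200
11,1.30400,0.34400,1.44900,0.03023,0.35430,0.06303,3.54500
12,2.45200,0.12430,2.75500,0.03687,0.15340,0.05423,5.57600
13,1.34600,0.95040,1.46500,0.06466,0.32780,0.11580,4.27000
14,1.77700,0.57650,1.12700,0.02988,0.23960,0.08358,3.83400
15,1.78600,0.61440,1.36400,0.03312,0.17140,0.05189,4.02100
16,2.89600,0.42200,2.68200,0.06387,0.58270,0.09963,6.74600
17,4.69000,1.02000,2.55100,0.10200,1.14900,0.15070,9.66300
18,1.04300,0.28110,1.57300,0.02553,0.12420,0.00000,3.04700
19,1.71700,0.63680,1.96200,0.08296,0.25020,0.15210,4.80100
20,2.28000,0.98300,2.53300,0.09785,0.34170,0.07771,6.31300
21,2.72900,0.34480,2.46400,0.04038,0.26460,0.02275,5.86600
22,4.20000,1.14700,3.44200,0.14280,0.61120,0.06122,9.60400
23,2.13900,0.16950,1.92900,0.00000,0.31460,0.01560,4.56800
24,2.74400,0.89550,2.32400,0.08142,0.73920,0.10810,6.89200
25,4.45000,1.84300,2.50900,0.09471,0.68730,0.07324,9.65700
26,2.81700,1.40100,2.60800,0.09266,0.95240,0.07638,7.94700
27,2.36800,0.55290,2.20200,0.05162,0.33050,0.07492,5.58000
28,1.48700,0.19820,1.88000,0.03231,0.19060,0.01684,3.80500
29,3.59900,0.68200,2.03000,0.04863,0.50450,0.06149,6.92600
30,2.11600,1.40900,3.49800,0.11720,0.31300,0.04773,7.50100
31,4.23700,1.20300,1.81800,0.03805,0.78120,0.06076,8.13800
32,2.07700,0.99350,2.65300,0.08411,0.31870,0.07907,6.20500
33,2.22100,1.10800,2.93100,0.10130,0.26470,0.06694,6.69300
34,1.86300,0.36300,0.94100,0.03012,0.34190,0.07997,3.61900
35,1.81800,0.30750,1.09600,0.00000,0.37170,0.12460,3.71800
36,2.13400,0.36860,1.07600,0.00000,0.18030,0.06089,3.82000
37,2.17300,1.30100,1.23200,0.04985,0.51130,0.12210,5.38900
38,3.77300,0.30780,3.22000,0.06403,0.36510,0.02726,7.75700
39,2.23400,0.40560,1.28900,0.00000,0.19850,0.03652,4.16400
40,2.16800,0.48230,1.77600,0.00000,0.27720,0.05842,4.76200
41,1.49000,0.48740,1.24000,0.00000,0.38200,0.12980,3.72900
42,1.70800,0.38800,1.58700,0.00000,0.34040,0.13020,4.15400
43,1.83400,0.29490,2.26100,0.03667,0.17050,0.02114,4.61800
44,2.19900,0.56150,2.56900,0.06130,0.26190,0.13020,5.78300
45,3.66700,1.33100,3.57200,0.12560,0.82100,0.08447,9.60100
46,1.98500,0.16710,1.61000,0.04060,0.11290,0.03844,3.95400
47,1.76500,0.20470,1.50800,0.03583,0.16990,0.00000,3.68300
48,2.36300,1.03000,2.51900,0.08953,0.69970,0.06263,6.76400
49,3.67000,1.31800,1.90000,0.11270,0.84670,0.18620,8.03400
50,2.44700,0.55160,1.77800,0.07714,0.43620,0.07921,5.36900
51,2.46600,1.46900,3.96100,0.22510,1.26700,0.30510,9.69300
52,4.41600,1.75600,2.84800,0.17540,0.95280,0.14630,10.30000
53,5.13600,1.29600,3.76900,0.17010,0.78040,0.07168,11.22000
54,1.90100,0.57970,0.95300,0.03516,0.29940,0.10780,3.87600
55,1.82500,0.34810,0.86700,0.03686,0.31720,0.09194,3.48600
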