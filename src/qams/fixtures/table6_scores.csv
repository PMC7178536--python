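batch,z
1,-2.2088
2,-0.8149
3,-0.3972
4,-1.2788
5,-1.3328
6,-1.4037
7,-2.187
8,-0.7398
9,-1.9465
10,-1.108
11,-1.8149
12,-1.5472
13,-0.1805
14,-1.5233
15,-1.794
16,0.6962
17,4.3433
18,-3.1265
19,0.1636
20,0.7331
21,-1.2827
22,3.0727
23,-2.39
24,1.723
25,3.4021
26,2.8143
27,-0.4977
28,-2.5341
29,0.3312
30,1.4697
31,1.6586
32,0.513
33,0.7921
34,-1.6345
35,-1.5166
36,-2.3571
37,0.8094
38,-0.0475
39,-2.3745
40,-1.7203
41,-1.2931
42,-1.2774
43,-2.0675
44,0.0793
45,3.6328
46,-2.35
47,-2.7293
48,1.3859
49,3.8177
50,-0.0636
51,7.7397
52,5.6501
53,4.5777
54,-1.1113
55,-1.5619
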