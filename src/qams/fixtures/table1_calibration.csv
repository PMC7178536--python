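code,name,compound_class,slope,intercept,r,range_min_ugml,range_max_ugml,lod_ugml,loq_ugml
GC,prim-O-glucosylcimifugin,glycoside,1815300,8028,0.9999,2.1,209.6,0.29,0.96
C,cimifugin,aglycone,2928940,7329,0.9999,1.22,122.0,0.28,0.92
GV,4'-O-beta-D-glucosyl-5-O-methylvisamminol,glycoside,1894482,14466,0.9999,3.34,334.0,0.28,0.94
V,5-O-methylvisamminol,aglycone,3222987,4879,0.9999,0.81,80.8,0.18,0.61
GH,sec-O-glucosylhamaudol,glycoside,2660022,6702,0.9999,1.64,163.6,0.22,0.73
H,hamaudol,aglycone,4418335,1757,0.9999,0.37,36.9,0.09,0.31
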