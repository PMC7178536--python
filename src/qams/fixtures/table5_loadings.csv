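code,z1,z2
GC,0.749,-0.365
C,0.866,0.122
GV,0.679,-0.58
V,0.9,-0.049
GH,0.903,0.184
H,0.599,0.733
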