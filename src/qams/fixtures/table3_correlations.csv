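analyte,pearson_r
GC,0.999996894
C,0.999998781
V,0.999996565
GH,0.99999876
H,0.999999518
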