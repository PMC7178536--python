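code,instrument_precision_rsd,intermediate_precision_rsd,stability_rsd,repeatability_rsd,mean_recovery,recovery_rsd
GC,0.75,2.4,0.84,1.03,99.87,1.66
C,0.56,1.69,0.56,0.73,97.34,0.77
GV,0.43,1.23,0.54,0.49,96.98,1.31
V,0.42,0.36,0.57,0.8,102.5,1.03
GH,0.37,1.06,0.34,0.96,98.13,0.71
H,0.67,1.45,0.69,1.35,99.48,0.68
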