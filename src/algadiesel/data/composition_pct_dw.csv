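strain,protein_pct_dw,carbohydrate_pct_dw,lipid_pct_dw
WS,22.66,26.12,24.43
M1,18.72,32.41,36.32
M2,22.97,25.60,38.59
M4,20.74,30.29,30.81
M5,23.85,38.64,33.56
M8,28.42,20.57,43.29
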