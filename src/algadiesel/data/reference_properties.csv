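strain,adu,kv,cn,iv,cp,density,hhv,db4plus_pct,c18_3_pct,lcsf,cfpp
WS,1.47,4.28,53.05,122.29,0.32,0.88,41.13,8.95,8.95,6.69,4.53
M1,1.23,4.43,54.65,104.48,3.51,0.88,40.71,0.00,0.00,7.40,6.78
M2,1.07,4.53,55.74,92.27,5.71,0.88,40.42,0.22,0.22,8.59,10.49
M4,1.20,4.45,54.85,102.26,3.91,0.88,40.65,4.95,4.94,7.61,7.44
M5,1.27,4.40,54.38,107.50,2.97,0.88,40.78,0.00,0.00,7.62,7.46
M8,0.87,4.66,57.09,77.19,8.41,0.88,40.06,0.00,0.00,11.23,18.82
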