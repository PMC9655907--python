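FA,WS,M1,M2,M4,M5,M8
C8:0,–,–,–,–,–,0.55
C10:0,1.06,–,–,–,–,1.14
C12:0,–,0.17,0.72,–,0.10,2.32
C14:0,0.18,0.26,0.23,0.23,0.16,0.44
C16:0,22.00,27.83,36.16,30.81,25.86,39.52
C18:0,3.06,5.20,8.09,4.27,5.48,9.10
C20:0,0.46,1.68,0.38,2.40,2.01,2.39
C22:0,1.09,0.12,0.18,–,0.12,0.23
C24:0,0.44,0.13,0.14,–,0.15,–
C26:0,–,–,–,–,0.05,–
C16:1 (ω7),–,1.49,1.25,2.18,0.70,0.49
C18:1 (ω7),4.46,2.06,–,–,2.85,2.73
C18:1,–,–,2.64,–,–,–
C18:1 (ω9),30.51,43.31,42.57,35.07,40.87,35.39
C20:1 (ω9),–,0.26,0.10,–,0.23,0.58
C16:2,1.67,1.28,0.38,2.61,1.05,–
C18:2 (ω6),25.28,13.66,6.91,16.61,18.03,4.40
C16:3,–,1.65,–,–,1.39,–
C18:3 (ω3),8.95,–,0.21,4.94,–,–
C22:4 (ω6),–,–,0.15,–,–,–
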