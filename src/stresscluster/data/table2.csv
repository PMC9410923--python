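id,M1,M2,M3,M4,M5,M6
A1,7.44,4.56,4.48,7.98,3.45,7.89
A2,3.15,7.38,7.26,5.01,6.38,5.06
A3,4.61,3.80,3.86,8.93,3.60,8.43
A4,7.05,4.55,8.78,4.44,4.43,6.61
A5,3.19,4.94,3.15,6.27,7.07,5.65
A6,8.42,8.29,4.55,3.72,7.31,5.61
A7,8.05,3.16,8.26,8.08,4.61,5.46
A8,8.68,6.63,5.90,6.10,6.53,6.53
A9,8.77,7.84,7.34,5.88,4.92,8.81
A10,7.87,3.13,8.98,8.36,6.53,7.68
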