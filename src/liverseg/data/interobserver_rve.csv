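case,Rad,Res1,Res2,Res3,RA
Patient1,8.89,6.56,11.73,4.20,0.70
Patient2,8.52,4.44,1.39,4.59,3.87
Patient3,1.84,4.42,2.45,5.57,5.41
Patient4,1.15,6.19,2.07,2.25,4.56
Patient5,4.72,0.24,3.47,0.93,0.93
Patient6,2.81,1.09,4.47,6.30,6.62
Patient7,3.49,0.26,1.17,3.56,3.32
Patient8,3.51,1.10,3.37,4.88,3.91
Patient9,2.27,0.87,0.09,2.11,2.62
Patient10,22.62,22.89,22.18,1.62,0.09
Patient11,7.24,2.69,2.12,0.78,0.87
Patient12,3.10,0.17,2.40,7.73,7.73
Patient13,2.24,0.79,5.97,7.86,6.72
Patient14,6.06,4.93,4.61,3.56,2.54
Patient15,11.39,5.24,6.50,0.52,0.43
Patient16,5.07,3.37,4.29,5.15,4.51
Patient17,1.13,1.34,4.21,2.66,2.62
Patient18,6.79,1.17,10.58,2.71,1.83
Patient19,9.14,4.28,2.49,1.57,1.38
Patient20,6.12,1.42,2.87,1.51,1.42
Patient21,4.31,2.30,0.49,3.91,3.93
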