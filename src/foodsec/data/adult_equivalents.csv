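age_lower,age_upper,male,female
0,1,0.33,0.33
1,2,0.46,0.46
2,3,0.54,0.54
3,5,0.62,0.62
5,7,0.74,0.70
7,10,0.84,0.72
10,12,0.88,0.78
12,14,0.96,0.84
14,16,1.06,0.86
16,18,1.14,0.86
18,30,1.04,0.80
30,60,1.00,0.82
60,inf,0.84,0.74
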