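gender,age_low,age_high,n,mean_saf,sd_saf
M,18,19,47,1.42,0.24
M,20,29,190,1.59,0.38
M,30,39,397,1.75,0.42
M,40,49,294,1.98,0.41
M,50,59,143,2.22,0.53
M,60,69,42,2.44,0.59
M,70,99,9,2.75,0.54
F,18,19,44,1.84,0.41
F,20,29,190,1.99,0.38
F,30,39,284,2.19,0.43
F,40,49,223,2.51,0.54
F,50,59,102,2.76,0.59
F,60,69,28,2.87,0.66
F,70,99,4,3.19,0.97
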