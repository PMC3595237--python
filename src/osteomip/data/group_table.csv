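gait,n,max_mean,max_sd,max_min,max_max,second_mean,second_sd,second_min,second_max
B,14,0.214,0.151,0.045,0.567,0.523,0.156,0.253,0.799
AQ,17,0.080,0.103,0.000,0.352,0.289,0.158,0.013,0.580
TQ,10,0.083,0.077,0.000,0.174,0.364,0.203,0.094,0.667
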