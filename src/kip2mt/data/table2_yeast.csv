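kip2_nM,tubulin_uM,growth_rate,growth_se,growth_n,cat_freq,cat_se,cat_n
0,4,0.257,0.004,300,0.234,0.017,191
5,4,0.302,0.005,263,0.137,0.012,141
10,4,0.353,0.008,146,0.103,0.010,116
20,4,0.572,0.01,57,0.020,0.006,13
40,4,0.589,0.012,48,0.009,0.004,5
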