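kip2_nM,tubulin_uM,length_um,length_se,length_n,growth_rate,growth_se,growth_n,cat_freq,cat_se,cat_n,cat_distance,cat_distance_se,shrink_rate,shrink_se,shrink_n,rescue_freq,rescue_se,rescue_n,rescue_distance,rescue_distance_se
0,12,1.0,0.1,54,0.32,0.02,172,0.166,0.015,126,1.9,0.2,27.6,1.0,130,0.88,0.33,7,32,12
1,12,1.0,0.2,75,0.37,0.01,152,0.126,0.012,104,2.9,0.3,27.7,0.9,85,0.20,0.14,2,140,100
2,12,2.1,0.2,88,0.35,0.01,159,0.135,0.013,115,2.6,0.3,29.7,0.9,110,0.54,0.24,5,55,25
5,12,5.3,0.2,82,0.62,0.03,77,0.065,0.011,33,10,2,28.4,1.8,45,2.2,0.7,9,13,4
10,12,6.4,0.2,75,0.78,0.03,38,0.043,0.011,16,18,5,29,4,18,1.8,0.7,6,16,6
20,12,7.7,0.3,68,0.99,0.04,36,0.020,0.006,10,50,16,,,,,,,,
40,12,8.8,0.6,26,0.94,0.05,18,0.004,,1,235,,,,,,,,,
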