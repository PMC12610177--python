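phase,item,endogenous_mg_d,endogenous_se,non_aa_mg_d,creatinine_mg_d,dander_mg_d,total_mg_d,pattern_pct
week6_7,Nitrogen,53.085,5.068,163.912,0.57,160.658,378.225,
week6_7,Asp,30.792,2.815,64.755,,59.282,154.829,6.549
week6_7,Glu,48.518,4.66,113.564,,100.119,262.201,11.091
week6_7,Ser,23.706,2.596,27.711,,85.005,136.422,5.771
week6_7,Arg,18.396,1.748,51.543,2.364,62.099,134.402,5.685
week6_7,Gly,82.767,7.94,73.071,1.019,72.35,229.207,9.696
week6_7,Thr,20.805,2.131,37.72,,43.297,101.822,4.307
week6_7,Pro,33.035,3.718,48.996,,102.179,184.21,7.793
week6_7,Ala,27.364,2.585,53.138,,42.61,123.112,5.208
week6_7,Val,23.47,2.298,37.382,,72.869,133.721,5.657
week6_7,Met,3.875,0.383,17.819,2.025,4.627,28.346,1.199
week6_7,Cys,10.282,1.344,7.916,,83.718,101.916,4.311
week6_7,Ile,20.083,2.916,32.55,,43.099,95.732,4.049
week6_7,Leu,29.266,2.867,56.276,,79.33,164.872,6.974
week6_7,Phe,18.751,1.669,31.888,,45.134,95.773,4.051
week6_7,His,4.371,0.399,20.175,,4.945,29.491,1.248
week6_7,Lys,17.613,1.916,55.669,,17.849,91.131,3.855
week6_7,Tyr,18.332,1.88,22.418,,25.43,66.18,2.8
week6_7,Trp,4.102,0.408,6.533,,4.593,15.228,0.644
week11_12,Nitrogen,70.351,8.047,168.502,0.789,377.823,617.465,
week11_12,Asp,39.233,4.115,66.569,,136.646,242.448,6.282
week11_12,Glu,62.601,7.336,116.744,,230.779,410.124,10.627
week11_12,Ser,31.53,3.653,28.487,,195.941,255.958,6.632
week11_12,Arg,24.064,2.797,52.987,3.271,143.14,223.462,5.79
week11_12,Gly,107.997,10.135,75.117,1.409,166.769,351.292,9.103
week11_12,Thr,27.567,3.232,38.777,,99.8,164.144,4.253
week11_12,Pro,43.308,4.795,50.368,,235.525,329.201,8.53
week11_12,Ala,34.668,3.917,54.626,,98.218,187.512,4.859
week11_12,Val,29.953,2.901,38.429,,167.966,236.345,6.124
week11_12,Met,5.062,0.789,18.318,2.802,10.666,36.848,0.955
week11_12,Cys,14.07,1.607,8.137,,192.973,215.18,5.576
week11_12,Ile,29.829,7.988,33.462,,99.344,162.635,4.214
week11_12,Leu,37.786,4.275,57.852,,182.858,278.496,7.216
week11_12,Phe,24.064,2.48,32.781,,104.035,160.88,4.169
week11_12,His,6.143,1.154,20.74,,11.398,38.281,0.992
week11_12,Lys,23.367,4.275,57.227,,41.143,121.737,3.154
week11_12,Tyr,24.448,3.166,23.046,,58.618,106.112,2.75
week11_12,Trp,5.41,0.593,6.716,,10.587,22.713,0.589
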