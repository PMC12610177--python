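compartment,age_days,amino_acid,mean_pct,se_pct,n
carcass,0,Asp,6.485,0.005,6
carcass,14,Asp,6.264,0.027,6
carcass,28,Asp,6.318,0.014,6
carcass,42,Asp,6.38,0.028,6
carcass,56,Asp,6.226,0.024,6
carcass,70,Asp,6.318,0.011,6
carcass,84,Asp,6.407,0.029,6
carcass,0,Glu,10.923,0.005,6
carcass,14,Glu,10.868,0.046,6
carcass,28,Glu,11.0,0.026,6
carcass,42,Glu,11.193,0.036,6
carcass,56,Glu,10.982,0.051,6
carcass,70,Glu,10.59,0.017,6
carcass,84,Glu,11.217,0.042,6
carcass,0,Ser,3.12,0.024,6
carcass,14,Ser,2.64,0.014,6
carcass,28,Ser,2.86,0.015,6
carcass,42,Ser,2.665,0.031,6
carcass,56,Ser,2.584,0.011,6
carcass,70,Ser,2.322,0.003,6
carcass,84,Ser,2.722,0.026,6
carcass,0,Arg,5.155,0.009,6
carcass,14,Arg,5.08,0.02,6
carcass,28,Arg,4.987,0.01,6
carcass,42,Arg,5.067,0.015,6
carcass,56,Arg,5.008,0.022,6
carcass,70,Arg,4.998,0.014,6
carcass,84,Arg,5.095,0.012,6
carcass,0,Gly,6.64,0.045,6
carcass,14,Gly,6.858,0.022,6
carcass,28,Gly,7.047,0.019,6
carcass,42,Gly,7.138,0.038,6
carcass,56,Gly,7.126,0.063,6
carcass,70,Gly,6.9,0.059,6
carcass,84,Gly,7.207,0.041,6
carcass,0,Thr,3.478,0.01,6
carcass,14,Thr,3.57,0.015,6
carcass,28,Thr,3.713,0.007,6
carcass,42,Thr,3.66,0.033,6
carcass,56,Thr,3.646,0.017,6
carcass,70,Thr,3.044,0.004,6
carcass,84,Thr,3.697,0.025,6
carcass,0,Pro,4.963,0.029,6
carcass,14,Pro,4.752,0.015,6
carcass,28,Pro,4.74,0.013,6
carcass,42,Pro,4.783,0.019,6
carcass,56,Pro,4.79,0.021,6
carcass,70,Pro,4.44,0.028,6
carcass,84,Pro,4.807,0.023,6
carcass,0,Ala,4.992,0.011,6
carcass,14,Ala,5.044,0.019,6
carcass,28,Ala,5.143,0.01,6
carcass,42,Ala,5.213,0.009,6
carcass,56,Ala,5.16,0.024,6
carcass,70,Ala,4.972,0.012,6
carcass,84,Ala,5.277,0.01,6
carcass,0,Val,4.07,0.011,6
carcass,14,Val,3.798,0.021,6
carcass,28,Val,3.62,0.01,6
carcass,42,Val,3.637,0.013,6
carcass,56,Val,3.668,0.015,6
carcass,70,Val,3.526,0.012,6
carcass,84,Val,3.59,0.018,6
carcass,0,Met,1.75,0.003,6
carcass,14,Met,1.712,0.009,6
carcass,28,Met,1.725,0.007,6
carcass,42,Met,1.758,0.012,6
carcass,56,Met,1.714,0.013,6
carcass,70,Met,1.7,0.007,6
carcass,84,Met,1.803,0.013,6
carcass,0,Cys,1.217,0.025,6
carcass,14,Cys,0.878,0.007,6
carcass,28,Cys,0.765,0.007,6
carcass,42,Cys,0.745,0.01,6
carcass,56,Cys,0.814,0.01,6
carcass,70,Cys,0.7,0.007,6
carcass,84,Cys,0.712,0.007,6
carcass,0,Ile,3.213,0.032,6
carcass,14,Ile,3.106,0.017,6
carcass,28,Ile,3.197,0.015,6
carcass,42,Ile,3.295,0.015,6
carcass,56,Ile,3.044,0.02,6
carcass,70,Ile,3.336,0.01,6
carcass,84,Ile,3.163,0.016,6
carcass,0,Leu,5.84,0.013,6
carcass,14,Leu,5.542,0.024,6
carcass,28,Leu,5.482,0.017,6
carcass,42,Leu,5.543,0.024,6
carcass,56,Leu,5.432,0.015,6
carcass,70,Leu,5.488,0.019,6
carcass,84,Leu,5.51,0.021,6
carcass,0,Phe,3.527,0.005,6
carcass,14,Phe,3.212,0.014,6
carcass,28,Phe,3.1,0.01,6
carcass,42,Phe,3.115,0.011,6
carcass,56,Phe,3.108,0.01,6
carcass,70,Phe,3.074,0.015,6
carcass,84,Phe,3.107,0.014,6
carcass,0,His,1.933,0.026,6
carcass,14,His,2.152,0.015,6
carcass,28,His,2.02,0.013,6
carcass,42,His,1.96,0.032,6
carcass,56,His,1.91,0.013,6
carcass,70,His,1.918,0.011,6
carcass,84,His,2.025,0.033,6
carcass,0,Lys,5.198,0.018,6
carcass,14,Lys,5.398,0.035,6
carcass,28,Lys,5.39,0.029,6
carcass,42,Lys,5.442,0.03,6
carcass,56,Lys,5.416,0.036,6
carcass,70,Lys,5.508,0.028,6
carcass,84,Lys,5.578,0.033,6
carcass,0,Tyr,2.49,0.015,6
carcass,14,Tyr,2.262,0.013,6
carcass,28,Tyr,2.258,0.011,6
carcass,42,Tyr,2.092,0.022,6
carcass,56,Tyr,2.215,0.014,6
carcass,70,Tyr,2.132,0.01,6
carcass,84,Tyr,2.152,0.017,6
carcass,0,Trp,0.748,0.005,6
carcass,14,Trp,0.676,0.004,6
carcass,28,Trp,0.598,0.005,6
carcass,42,Trp,0.617,0.004,6
carcass,56,Trp,0.688,0.006,6
carcass,70,Trp,0.606,0.003,6
carcass,84,Trp,0.595,0.007,6
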