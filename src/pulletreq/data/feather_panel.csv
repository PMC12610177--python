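compartment,age_days,amino_acid,mean_pct,se_pct,n
feather,0,Asp,6.002,0.083,6
feather,14,Asp,5.672,0.018,6
feather,28,Asp,5.798,0.013,6
feather,42,Asp,5.558,0.041,6
feather,56,Asp,5.528,0.031,6
feather,70,Asp,5.665,0.016,6
feather,84,Asp,5.655,0.022,6
feather,0,Glu,8.318,0.034,6
feather,14,Glu,9.12,0.034,6
feather,28,Glu,9.553,0.033,6
feather,42,Glu,9.275,0.071,6
feather,56,Glu,9.293,0.051,6
feather,70,Glu,9.578,0.03,6
feather,84,Glu,9.583,0.03,6
feather,0,Ser,7.792,0.06,6
feather,14,Ser,7.418,0.051,6
feather,28,Ser,8.08,0.059,6
feather,42,Ser,8.522,0.09,6
feather,56,Ser,7.793,0.055,6
feather,70,Ser,8.0,0.049,6
feather,84,Ser,8.378,0.05,6
feather,0,Arg,6.99,0.045,6
feather,14,Arg,5.9,0.01,6
feather,28,Arg,5.688,0.011,6
feather,42,Arg,5.525,0.048,6
feather,56,Arg,5.647,0.033,6
feather,70,Arg,6.13,0.02,6
feather,84,Arg,5.855,0.015,6
feather,0,Gly,6.875,0.045,6
feather,14,Gly,6.658,0.019,6
feather,28,Gly,6.618,0.015,6
feather,42,Gly,6.563,0.04,6
feather,56,Gly,6.638,0.035,6
feather,70,Gly,7.067,0.009,6
feather,84,Gly,6.843,0.025,6
feather,0,Thr,3.683,0.007,6
feather,14,Thr,4.017,0.009,6
feather,28,Thr,4.115,0.009,6
feather,42,Thr,4.157,0.037,6
feather,56,Thr,3.988,0.021,6
feather,70,Thr,4.172,0.016,6
feather,84,Thr,4.143,0.013,6
feather,0,Pro,8.613,0.047,6
feather,14,Pro,8.57,0.011,6
feather,28,Pro,9.368,0.025,6
feather,42,Pro,9.105,0.082,6
feather,56,Pro,9.488,0.065,6
feather,70,Pro,9.733,0.039,6
feather,84,Pro,9.822,0.032,6
feather,0,Ala,2.882,0.015,6
feather,14,Ala,3.743,0.011,6
feather,28,Ala,4.037,0.012,6
feather,42,Ala,3.943,0.025,6
feather,56,Ala,3.957,0.027,6
feather,70,Ala,4.082,0.005,6
feather,84,Ala,4.07,0.022,6
feather,0,Val,5.732,0.04,6
feather,14,Val,5.98,0.008,6
feather,28,Val,6.542,0.023,6
feather,42,Val,6.157,0.062,6
feather,56,Val,6.643,0.054,6
feather,70,Val,7.167,0.027,6
feather,84,Val,6.882,0.022,6
feather,0,Met,0.322,0.003,6
feather,14,Met,0.493,0.004,6
feather,28,Met,0.48,0.003,6
feather,42,Met,0.493,0.004,6
feather,56,Met,0.437,0.003,6
feather,70,Met,0.443,0.004,6
feather,84,Met,0.435,0.003,6
feather,0,Cys,7.177,0.035,6
feather,14,Cys,7.14,0.049,6
feather,28,Cys,8.653,0.065,6
feather,42,Cys,8.855,0.104,6
feather,56,Cys,7.92,0.049,6
feather,70,Cys,7.632,0.048,6
feather,84,Cys,8.277,0.061,6
feather,0,Ile,3.89,0.028,6
feather,14,Ile,3.607,0.01,6
feather,28,Ile,4.007,0.013,6
feather,42,Ile,3.83,0.045,6
feather,56,Ile,4.01,0.031,6
feather,70,Ile,4.055,0.012,6
feather,84,Ile,4.19,0.015,6
feather,0,Leu,6.875,0.033,6
feather,14,Leu,6.82,0.007,6
feather,28,Leu,7.517,0.018,6
feather,42,Leu,7.142,0.06,6
feather,56,Leu,7.377,0.051,6
feather,70,Leu,7.562,0.024,6
feather,84,Leu,7.61,0.026,6
feather,0,Phe,5.093,0.034,6
feather,14,Phe,4.103,0.007,6
feather,28,Phe,4.243,0.007,6
feather,42,Phe,4.07,0.035,6
feather,56,Phe,4.183,0.026,6
feather,70,Phe,4.31,0.015,6
feather,84,Phe,4.335,0.014,6
feather,0,His,1.967,0.041,6
feather,14,His,0.847,0.009,6
feather,28,His,0.513,0.009,6
feather,42,His,0.458,0.004,6
feather,56,His,0.477,0.007,6
feather,70,His,0.457,0.005,6
feather,84,His,0.473,0.007,6
feather,0,Lys,1.503,0.018,6
feather,14,Lys,2.02,0.024,6
feather,28,Lys,1.93,0.023,6
feather,42,Lys,1.905,0.013,6
feather,56,Lys,1.697,0.015,6
feather,70,Lys,1.693,0.022,6
feather,84,Lys,1.683,0.018,6
feather,0,Tyr,4.26,0.023,6
feather,14,Tyr,2.892,0.017,6
feather,28,Tyr,2.632,0.01,6
feather,42,Tyr,2.583,0.024,6
feather,56,Tyr,2.402,0.016,6
feather,70,Tyr,2.382,0.016,6
feather,84,Tyr,2.448,0.013,6
feather,0,Trp,0.617,0.007,6
feather,14,Trp,0.565,0.005,6
feather,28,Trp,0.498,0.002,6
feather,42,Trp,0.467,0.004,6
feather,56,Trp,0.433,0.006,6
feather,70,Trp,0.433,0.002,6
feather,84,Trp,0.44,0.003,6
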