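amino_acid,age_days,requirement_g_d
Asp,0,0.1
Asp,14,0.256
Asp,28,0.388
Asp,42,0.456
Asp,56,0.742
Asp,70,0.812
Asp,84,0.863
Glu,0,0.17
Glu,14,0.501
Glu,28,0.736
Glu,42,0.854
Glu,56,1.304
Glu,70,1.421
Glu,84,1.503
Ser,0,0.143
Ser,14,0.422
Ser,28,0.621
Ser,42,0.715
Ser,56,0.693
Ser,70,0.758
Ser,84,0.806
Arg,0,0.165
Arg,14,0.538
Arg,28,0.783
Arg,42,0.891
Arg,56,0.619
Arg,70,0.678
Arg,84,0.721
Gly,0,0.258
Gly,14,0.792
Gly,28,1.131
Gly,42,1.279
Gly,56,0.991
Gly,70,1.081
Gly,84,1.147
Thr,0,0.095
Thr,14,0.301
Thr,28,0.44
Thr,42,0.507
Thr,56,0.413
Thr,70,0.453
Thr,84,0.482
Pro,0,0.253
Pro,14,0.743
Pro,28,1.056
Pro,42,1.207
Pro,56,1.043
Pro,70,1.137
Pro,84,1.206
Ala,0,0.131
Ala,14,0.438
Ala,28,0.632
Ala,42,0.718
Ala,56,0.481
Ala,70,0.527
Ala,84,0.561
Val,0,0.144
Val,14,0.446
Val,28,0.646
Val,42,0.737
Val,56,0.629
Val,70,0.688
Val,84,0.731
Met,0,0.023
Met,14,0.075
Met,28,0.109
Met,42,0.124
Met,56,0.077
Met,70,0.085
Met,84,0.09
Cys,0,0.102
Cys,14,0.305
Cys,28,0.436
Cys,42,0.498
Cys,56,0.587
Cys,70,0.642
Cys,84,0.682
Ile,0,0.086
Ile,14,0.273
Ile,28,0.398
Ile,42,0.458
Ile,56,0.39
Ile,70,0.428
Ile,84,0.455
Leu,0,0.209
Leu,14,0.647
Leu,28,0.934
Leu,42,1.067
Leu,56,0.852
Leu,70,0.93
Leu,84,0.987
Phe,0,0.086
Phe,14,0.276
Phe,28,0.403
Phe,42,0.464
Phe,56,0.387
Phe,70,0.424
Phe,84,0.451
His,0,0.024
His,14,0.079
His,28,0.116
His,42,0.133
His,56,0.081
His,70,0.089
His,84,0.095
Lys,0,0.08
Lys,14,0.282
Lys,28,0.407
Lys,42,0.462
Lys,56,0.307
Lys,70,0.337
Lys,84,0.358
Tyr,0,0.05
Tyr,14,0.17
Tyr,28,0.247
Tyr,42,0.283
Tyr,56,0.227
Tyr,70,0.249
Tyr,84,0.265
Trp,0,0.011
Trp,14,0.036
Trp,28,0.052
Trp,42,0.06
Trp,56,0.048
Trp,70,0.053
Trp,84,0.056
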