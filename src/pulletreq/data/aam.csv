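phase,amino_acid,pct
week6_7,Asp,6.549
week6_7,Glu,11.091
week6_7,Ser,5.771
week6_7,Arg,5.685
week6_7,Gly,9.696
week6_7,Thr,4.307
week6_7,Pro,7.793
week6_7,Ala,5.208
week6_7,Val,5.657
week6_7,Met,1.199
week6_7,Cys,4.311
week6_7,Ile,4.049
week6_7,Leu,6.974
week6_7,Phe,4.051
week6_7,His,1.248
week6_7,Lys,3.855
week6_7,Tyr,2.8
week6_7,Trp,0.644
week11_12,Asp,6.282
week11_12,Glu,10.627
week11_12,Ser,6.632
week11_12,Arg,5.79
week11_12,Gly,9.103
week11_12,Thr,4.253
week11_12,Pro,8.53
week11_12,Ala,4.859
week11_12,Val,6.124
week11_12,Met,0.955
week11_12,Cys,5.576
week11_12,Ile,4.214
week11_12,Leu,7.216
week11_12,Phe,4.169
week11_12,His,0.992
week11_12,Lys,3.154
week11_12,Tyr,2.75
week11_12,Trp,0.589
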