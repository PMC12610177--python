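amino_acid,pct
Asp,5.616
Glu,9.485
Ser,8.057
Arg,5.877
Gly,6.849
Thr,4.101
Pro,9.681
Ala,4.036
Val,6.897
Met,0.438
Cys,7.943
Ile,4.085
Leu,7.516
Phe,4.276
His,0.469
Lys,1.691
Tyr,2.411
Trp,0.436
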