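amino_acid,pct
Asp,6.308
Glu,11.058
Ser,2.703
Arg,5.02
Gly,7.104
Thr,3.673
Pro,4.771
Ala,5.172
Val,3.642
Met,1.732
Cys,0.775
Ile,3.179
Leu,5.486
Phe,3.108
His,1.963
Lys,5.416
Tyr,2.183
Trp,0.634
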