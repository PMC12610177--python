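phase,amino_acid,loss_mg_d,se
week6_7,Asp,30.792,2.815
week6_7,Glu,48.518,4.66
week6_7,Ser,23.706,2.596
week6_7,Arg,18.396,1.748
week6_7,Gly,82.767,7.94
week6_7,Thr,20.805,2.131
week6_7,Pro,33.035,3.718
week6_7,Ala,27.364,2.585
week6_7,Val,23.47,2.298
week6_7,Met,3.875,0.383
week6_7,Cys,10.282,1.344
week6_7,Ile,20.083,2.916
week6_7,Leu,29.266,2.867
week6_7,Phe,18.751,1.669
week6_7,His,4.371,0.399
week6_7,Lys,17.613,1.916
week6_7,Tyr,18.332,1.88
week6_7,Trp,4.102,0.408
week11_12,Asp,39.233,4.115
week11_12,Glu,62.601,7.336
week11_12,Ser,31.53,3.653
week11_12,Arg,24.064,2.797
week11_12,Gly,107.997,10.135
week11_12,Thr,27.567,3.232
week11_12,Pro,43.308,4.795
week11_12,Ala,34.668,3.917
week11_12,Val,29.953,2.901
week11_12,Met,5.062,0.789
week11_12,Cys,14.07,1.607
week11_12,Ile,29.829,7.988
week11_12,Leu,37.786,4.275
week11_12,Phe,24.064,2.48
week11_12,His,6.143,1.154
week11_12,Lys,23.367,4.275
week11_12,Tyr,24.448,3.166
week11_12,Trp,5.41,0.593
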