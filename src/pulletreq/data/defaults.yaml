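# Default sub-model parameters of the factorial requirement model for
# Hy-Line Gray pullets, 0-84 days. Units: weights g, ages days,
# maintenance coefficient mg protein / g^0.75 / day, digestibility
# coefficients on the fraction scale.
growth:
  family: von_bertalanffy
  A: 1412.418
  b: 0.748
  k: 0.024
allometry:
  carcass:
    form: power
    b0: 0.181
    b1: 1.007
  feather:
    form: quadratic
    b0: -3.393
    b1: 0.089
    b2: -1.46e-5
maintenance:
  brooding:
    phase: week6_7
    C: 21.665
  early_growing:
    phase: week11_12
    C: 23.950
  phase_boundary_days: 42
digestibility:
  protein:
    family: logarithmic
    c0: 0.577
    c1: 0.037
  amino_acid:
    family: logarithmic
    c0: 0.860
    c1: 0.004
composition:
  carcass_window: [28, 42, 56]
  feather_window: [56, 70, 84]
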