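# Methods

## Model overview

`pulletreq` computes the daily dietary requirement of 18 amino acids for
a growing laying-hen pullet between hatch and 84 days by the factorial
method: the requirement is the sum of what the bird needs to replace
obligatory losses (maintenance) and what it deposits in new carcass and
feather protein (growth), each divided by the apparent digestibility of
the dietary supply. Two core assumptions are inherited from the factorial
tradition: (1) the requirement decomposes additively into maintenance and
growth; (2) the amino-acid composition of deposited protein is constant
over the modelled window, so deposition scales patterns measured once.

The components:

* **Growth.** Body weight follows a Von Bertalanffy curve
  `BW(t) = A(1 − b·e^(−kt))³` (A mature weight in g, b dimensionless
  shape with 0 < b < 1, k per day). Gompertz and Logistic curves are
  fitted as competitors and ranked by AIC (ties by BIC, then R²). The
  inflection analytics are closed forms: `t* = ln(3b)/k`, `W* = 8A/27`
  for Von Bertalanffy; `ln(b)/k` with `A/e` (Gompertz) or `A/2`
  (Logistic).
* **Deposition.** Carcass protein follows a power allometry
  `CP = b₀·BW^b₁`; feather protein a quadratic
  `FP = b₀ + b₁·BW + b₂·BW²`. Deposition rates are analytic chain-rule
  derivatives through the growth curve; for the power∘Von-Bertalanffy
  composition the rate is `K·e^(−kt)·(1 − b·e^(−kt))^(3b₁−1)` with
  `K = b₀·b₁·3·A^b₁·b·k`, and for the quadratic composition
  `k·e^(−kt)·[3Ab·b₁·u² + 6A²b·b₂·u⁵]`, `u = 1 − b·e^(−kt)`. The
  reference parameters give K ≈ 14.587 and term constants ≈ 282.082 and
  ≈ −130.717 g/day; these are derived at run time, never hard-coded.
* **Maintenance.** Paired nitrogen-free / low-nitrogen balance trials at
  6–7 and 11–12 weeks partition obligatory nitrogen losses into
  endogenous excretion (EN, the nitrogen-free group's excretion),
  surface/feather-dander loss (NR, the low-nitrogen group's apparent
  "retention"), and creatinine. The maintenance coefficient is
  `C = (EN + NR)·6.25 / meanBW^0.75` in mg crude protein per g^0.75
  metabolic weight per day, with meanBW from the low-nitrogen group. The
  6–7-week result represents the whole brooding phase (0–6 wk) and the
  11–12-week result the early-growing phase (7–12 wk).
* **Maintenance pattern.** Per amino acid, maintenance loss is assembled
  from four routes: measured endogenous free amino acids; creatinine
  converted mole-for-mole to its Arg/Gly/Met precursors
  (creatinine 113.118 g/mol, 3 N); the non-amino-acid nitrogen residue
  (EN − AA-form N − creatinine N) expressed as crude protein (× 6.25)
  and distributed with the carcass pattern; and the dander loss
  (NR × 6.25) distributed with the feather pattern. The pattern AAm is
  each total as a percentage of total maintenance crude protein.
* **Digestibility.** Apparent digestibility from the acid-insoluble-ash
  internal marker:
  `d = 1 − (AIA_feed/AIA_feces)·(nutrient_feces/nutrient_feed)`. Age
  trends are fitted with logarithmic, exponential and quadratic
  candidates; the logarithmic curves `APD = 0.577 + 0.037·ln t` and
  `AAD = 0.860 + 0.004·ln t` are the reference parameterisation.
* **Integration.** Maintenance is divided by the pooled amino-acid
  digestibility AAD and both growth terms by the protein digestibility
  APD — an asymmetry retained deliberately from the source model. The
  maintenance product `C·BW^0.75` is in mg/day and divided by 1000;
  deposition rates are already g/day.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| A, b, k | g, –, day⁻¹ | 1412.418, 0.748, 0.024 | reference Von Bertalanffy fit |
| carcass b₀, b₁ | –, – | 0.181, 1.007 | reference power allometry |
| feather b₀, b₁, b₂ | g, –, g⁻¹ | −3.393, 0.089, −1.46e−5 | reference quadratic |
| C (brooding / early-growing) | mg·g^−0.75·d⁻¹ | 21.665 / 23.950 | balance-trial coefficients |
| APD c₀, c₁; AAD c₀, c₁ | fraction | 0.577, 0.037; 0.860, 0.004 | logarithmic digestibility trends |
| phase boundary | days | 42 (inclusive to brooding) | provenance of the 42-day column is ambiguous; configurable |
| pattern windows | days | carcass 28/42/56, feather 56/70/84 | ages at which the patterns have stabilised |

Amino-acid stoichiometry uses free amino-acid molar masses (Cys as
cysteine, 121.16 g/mol, 1 N), nitrogen at 14.007 g/mol and the
conventional crude-protein factor 6.25.

## Numerical and design choices

* **Fitting.** Nonlinear least squares (Levenberg–Marquardt /
  trust-region via `scipy.optimize.curve_fit` with analytic Jacobians;
  linear algebra for polynomial forms). Starting values are
  deterministic: A = 1.1·max(BW), k = 0.03, b solved from the earliest
  observation. Parameter SEs are asymptotic (Jacobian at the optimum);
  95% CIs use the t quantile with n − p degrees of freedom. RMSE is
  √(RSS/n). Information criteria use the Gaussian-likelihood least-squares
  form AIC = n·ln(RSS/n) + 2(p+1), BIC with (p+1)·ln n; they serve
  comparisons on a common data set, not absolute value matching.
* **Form selection** (allometry, digestibility) ranks by R² compared at
  3-decimal precision with AIC breaking ties. Exact R² comparison would
  let the extra quadratic parameter win every noisy comparison; at the
  reported precision the nested forms tie and AIC's parameter penalty
  decides. Note a genuine near-degeneracy: with carcass exponent
  b₁ = 1.007 the power and linear forms are practically
  indistinguishable on noisy data — the selection then resolves by
  residual luck, which is why the reference comparison itself shows
  three forms at R² = 0.998.
* **Digestibility clamps.** Ages below 1 day are clamped to 1 before the
  logarithm (the day-0 ration is evaluated at day-1 digestibility) and
  predictions are clamped to [0, 1]. Fitting rejects ages < 1 rather
  than clamping training data.
* **Phase switch.** The maintenance coefficient and pattern switch at
  the phase boundary (default 42 days, boundary age belongs to
  brooding). The requirement is continuous everywhere else;
  `phase_boundary_jump` quantifies the per-amino-acid discontinuity.
* **Negative feather mass.** The feather quadratic predicts negative
  protein mass below ~40 g live weight. Mass predictions are not
  clamped; the requirement model only consumes the deposition *rate*,
  which stays positive over the study range.
* **AA-form nitrogen scalar.** The published per-amino-acid endogenous
  losses do not reproduce the published AA-form nitrogen totals under
  free-amino-acid stoichiometry (≈60.9 vs 53.085 mg/day in the brooding
  phase). `build_maintenance_table` therefore defaults to the
  measured-scalar mode (the published totals as inputs) and offers a
  stoichiometric mode; both are exercised in tests and the discrepancy
  is surfaced, not resolved.
* **Duncan's test** is provided for completeness of the age-stability
  analysis (studentized-range quantiles at protection level
  1 − (1−α)^(p−1)); the pattern windows are configuration, not derived
  from the letters.

## Synthetic data generator

No bird-level raw data are published, so `pulletreq.simulate` generates
the four observation streams from the reference parameters as ground
truth, emulating the trial design: 6 replicate groups weighed
fortnightly 0–84 days (multiplicative Gaussian body-weight noise, sd 2%);
per-age dissection records with additive Gaussian protein noise (sd 2 g),
starting at 14 days because below ~40 g the feather quadratic's mass is
negative and hatch-day records would only contribute floored zeros;
nitrogen-balance group means perturbed at 1× their reported SEs;
digestibility quadruples (fixed feed concentrations, fecal concentration
solved) whose implied digestibility equals the truth curve plus additive
noise at the two curves' reported residual scales (protein 0.015, pooled
amino acid 0.003). All noise is Gaussian — the source reports only
means ± SE, so no heavier-tailed structure is claimed. A single seed
drives every stream through independent, stably-keyed generators.

What passing on synthetic data does and does not show: it validates the
estimators (exact recovery at zero noise, calibrated CIs and unbiased
recovery at the reported noise scales) and the integration (a zero-noise
end-to-end fit reproduces the truth-parameter requirement table to
1e−6 relative). It does not validate the model against independent
bird data, does not capture between-bird correlation, mortality, feed
intake effects or non-Gaussian measurement error.

## Problem sizes

Simulation-based tests use the study's own scale: 42 weight records per
replicate fit, 100–200 replicates for recovery and selection rates, 500
for the maintenance-coefficient distribution. The whole suite runs in a
few seconds on one CPU.

## Known limitations

* The published per-age requirement table is **not** reproducible
  cell-wise from the published sub-models (e.g. Asp at 84 days
  recomposes to ≈0.48 g/day against a published 0.863; methionine agrees
  within ~4%). The origin of the discrepancy is not disclosed in the
  source; the package emits a side-by-side diff report and asserts only
  structural properties (additivity, homogeneity, digestibility
  monotonicity, continuity off the phase boundary) plus scale/ordering
  agreement (day-0 magnitudes, 84-day extremes).
* The published Logistic inflection weight (395.891 g) is inconsistent
  with A/2 for the published A (1076.032 g); the closed form A/2 is
  implemented and the inconsistency only documented.
* Apparent (not standardized ileal) digestibility is modelled;
  microbial fermentation is uncorrected. No egg-production component,
  no energy requirements, no lipid/ash/water compartments, no
  mixed-effects growth modelling.
* Whether the published patterns were computed from rounded or unrounded
  cell means is unknown; pattern reproductions are held to ±0.01
  percentage points (±0.35 for the reconstructed maintenance patterns,
  whose published dander column deviates a few percent from
  NR × 6.25 × AAf).
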