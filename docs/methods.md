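# Methods

## Model

Scattering from a solution of monodisperse particles at number density n
is I(Q) = n·P(Q)·S(Q). At low Q both factors admit Gaussian (Guinier-type)
asymptotes:

- form factor: P(Q) ≈ P(0)·exp(−Q²R_g²/3), with R_g² the mean-square
  distance of the excess scattering-length density from its center;
- structure factor: S(Q) ≈ S(0)·exp(−⅙·((S(0)−1)/S(0))·Q²R_i²), with
  R_i² = ∫h(r)r²d³r / ∫h(r)d³r the mean-square distance of the total
  correlation function h(r) = g(r) − 1. In radial form the ratio is
  ∫h r⁴dr / ∫h r²dr.

Their product is again a Gaussian, so a classical Guinier fit at finite
concentration returns an apparent radius obeying

R_g,obs² = R_g,0² + ξ·R_i², ξ = ½(S(0)−1)/S(0).

In the dilute regime S(0) = 1 − 2nB₂₂ and ξ = −nB₂₂/(1−2nB₂₂) ≈ −nB₂₂.
The inversion is two weighted straight-line fits after the per-profile
Guinier stage: I(0)/n vs n gives B₂₂ = −a/2b; R_g,obs² vs −nB₂₂ gives
R_i² (slope) and R_g,0² (intercept). For anisotropic solutes the working
equations are formally identical (the orientational averages fold into
the same S(0) and R_i²), so no separate code path exists.

In the dilute limit h(r) is the Mayer function e^(−βV)−1, which connects
R_i (and B₂₂ = −½∫h·4πr²dr) to a pair potential; for weak potentials the
Mayer weight linearizes to −βV and R_i² ≈ ∫V r⁴dr / ∫V r²dr. Hard-sphere
closed forms (R_i = √(3/5)σ, B₂₂ = (2π/3)σ³, R_i = 2R_g,HS) anchor every
quadrature path.

## Assumptions

- Monodisperse solute; no resolution smearing; flat incoherent background.
- The low-Q window satisfies Q·R_g,obs ≲ 1 and Q·R_i ≲ 0.5–1 so both
  Gaussian asymptotes hold; the virial relation S(0) = 1 − 2nB₂₂ further
  assumes 2n|B₂₂| ≪ 1.
- Intensity uncertainties are 1σ counting errors; ln-space fitting uses
  σ_ln I = dI/I (delta method).

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| Guinier window | Å⁻¹ | 0.015–0.07 | standard low-Q window for a ~13 Å protein; overridable, with a `window_sweep` sensitivity table |
| Q·R_g guard | — | warn above 1.3 | conventional validity bound; a warning, not an error, since well-behaved fits reach ~1.0 |
| background window | Å⁻¹ | 0.35–0.45 | flat high-Q region for small proteins on a 0.007–0.85 Å⁻¹ range; subtracted as a single window-mean constant |
| interaction abscissa `x_mode` | — | `dilute` (−nB₂₂) | matches the standard presentation; `xi_exact` uses −nB₂₂/(1−2nB₂₂) and is exact at zero noise |
| mass density ρ | g/cm³ | 1.46 | appropriate for a small protein like lysozyme (density is molecular-weight dependent); only used for volume fractions |
| N_A | 1/mol | 6.02214076×10²³ | exact |
| quadrature tolerance | — | 1e-9 abs+rel | discontinuity radii (σ, λσ, table knots) are mandatory subdivision points; hard cores break global adaptive schemes otherwise |

## Synthetic data generator

`sasri.synthetic` produces exactly the statistical structure the analysis
assumes: per concentration, I = n·P·S with the Guinier-exponential (or
uniform-sphere) P and the low-Q asymptotic S parameterized by
(S(0) = 1−2nB₂₂, R_i); heteroscedastic Gaussian noise with counting-like
scaling σ(Q) = noise_frac·√(I(Q)·I(0)). Defaults emulate a dilute
lysozyme series: six concentrations 2.45–18.56 mg/mL, M_W = 14.3 kDa,
R_g,0 = 13 Å, R_i = 38 Å, B₂₂ = −3.8×10⁻²⁰ mL, Q from 0.007 to 0.85 Å⁻¹
(120 log-spaced points), noise 1% of I(0) where noise is requested.

What it does **not** emulate: instrument resolution smearing, multiple
scattering, polydispersity, Q-dependent backgrounds, inter-detector
stitching artifacts, or beamstop contamination at the lowest Q. Passing
tests therefore demonstrate the estimator's correctness and noise
behavior under the model's own assumptions, not robustness to every real
reduction artifact. One deliberate misspecification probe exists: the
`square_well_numeric` form replaces the asymptotic S(Q) by the exact
radial Fourier transform of a dilute square-well Mayer function.

## Numerical choices

- All line fits share one centered weighted-least-squares kernel: the
  abscissa is shifted to its weighted mean before solving, which keeps the
  normal equations conditioned even when x spans ~10¹⁷ (number densities).
  With supplied σ the parameter covariance is the unscaled inverse normal
  matrix; unweighted fits scale it by residual variance (OLS convention).
- Guinier fits exclude in-window points with I ≤ 0 (background
  subtraction can push weak points negative) rather than failing; fewer
  than 5 usable points is an error. A non-negative slope raises a
  "no Guinier decay" error — R_g is undefined, not zero.
- B₂₂ uncertainty propagates from the full (a, b) covariance including
  the correlation term; the uncertainty of n itself is neglected
  (concentration errors are ≲1.4% in the emulated conditions).
- σ(R_g,obs²) = 2·R_g,obs·σ(R_g,obs), first order.
- A negative fitted R_i² is **reported** with R_i flagged undefined
  (NaN), never clipped — it is the primary diagnostic that a series
  carries no resolvable interaction signal.
- R_i quadratures reject ill-conditioned ratios: if |∫w r²dr| is below
  10⁻⁶ of ∫|w| r²dr (sign cancellation) or the magnitude integral itself
  vanishes (ideal gas), an error is raised instead of an unstable number.
- Weak-mode R_i is refused for potentials with a hard core (V is not
  small there); the Mayer mode handles cores exactly.
- The Zimm surface fit works on relative residuals (model/y − 1) with
  P(0) parameterized relative to its data-derived guess and B₂₂ scaled by
  1/(2n_max), so all fit parameters are O(1–10); errors come from the
  Jacobian at the solution scaled by residual variance.
- Tabulated potentials are linearly interpolated; absolute-energy tables
  (J, kJ/mol, kcal/mol) are converted to k_BT units on ingestion using
  the supplied temperature. A potential-of-mean-force table ω(r) goes
  through the same pathway — the integrals are identical; the caller
  asserts the interpretation.

## Design choices

- **Two-stage route is primary; Zimm fit is a cross-check.** The modified
  Zimm surface fit estimates the same (R_g,0, R_i, B₂₂) in one shot, but
  it is kept as an independent estimator whose agreement with the primary
  route is a test, never merged into it.
- **Default abscissa −nB₂₂, exact ξ optional.** At the emulated
  concentrations the two differ by <6%; the choice is recorded in the
  result object. Exact-recovery tests use the exact ξ, because the
  forward model is built from it and the dilute abscissa is then mildly
  nonlinear by construction.
- **Fits in ln-space, not nonlinear exponential fits**, matching standard
  Guinier practice and making the exactness properties (machine-precision
  recovery on exact model data) provable.
- **Sphere truncation bias is upward.** For a uniform sphere
  ln P = −x²/5 − x⁴/350 (x = QR): the Q⁴ coefficient is negative, so
  widening the window steepens the fitted slope and biases R_g,obs high —
  +0.5% at Q·R_g = 0.7 rising to +1.9% at 1.3. The window-sweep tests
  assert this computed direction and the monotone shrinkage of the bias
  with the window.
- **Units are fixed** (Å⁻¹, mg/mL, mL) rather than auto-detected; a
  `q_unit="1/nm"` read flag is the only conversion. Silent unit guessing
  is a classic source of wrong sizes.

## Problem sizes

The Monte-Carlo recovery study in the acceptance tests uses 200
replicates of a six-concentration series at 1% noise (runs in seconds);
the ordering studies use 40–60 replicates. These sizes give stable
medians and orderings for the properties asserted.

## Known limitations

- No resolution smearing: wavelength-spread effects on R_g,obs are not
  modeled, so absolute values from heavily smeared instruments will carry
  that bias.
- The virial stage assumes the dilute relation S(0) = 1 − 2nB₂₂; strongly
  interacting or concentrated systems need the general ξ form with an
  independently measured S(0).
- Polydispersity is not handled; R_i for polydisperse systems would need
  a modified estimator.
- The weak-potential R_i ratio is undefined for sign-balanced potentials
  (∫V d³r ≈ 0); the code surfaces this as an error rather than choosing a
  regularization.
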