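# sasri

Modified Guinier analysis of small-angle scattering concentration series:
apparent radius of gyration, second osmotic virial coefficient **B₂₂**,
infinite-dilution radius of gyration **R_g,0**, and the model-independent
**radius of interparticle interaction R_i** — plus R_i and B₂₂ computed
from isotropic pair potentials by quadrature.

## The problem

Classical Guinier analysis fits the low-Q scattering of a dilute solution,

    I(Q) ≈ I(0)·exp(−Q²R_g²/3),

and reads off the radius of gyration. It assumes the structure factor
S(Q) = 1. At any finite concentration that is not quite true, and the
fitted radius is an *apparent* value R_g,obs that drifts with
concentration. Expanding S(Q) at low Q the same way Guinier expanded P(Q)
gives

    S(Q) ≈ S(0)·exp(−⅙·((S(0)−1)/S(0))·Q²R_i²),

where R_i² = ∫h(r) r² d³r / ∫h(r) d³r is the mean-square distance of the
total correlation function h(r) = g(r) − 1 — the length scale over which
interparticle interactions displace the solution from the ideal-gas
configuration. Combining the two expansions:

    R_g,obs² = R_g,0² + ξ·R_i²,    ξ = ½·(S(0) − 1)/S(0),

and in the dilute regime S(0) = 1 − 2nB₂₂, so ξ ≈ −nB₂₂ and

    R_g,obs² ≈ R_g,0² − nB₂₂·R_i².

A concentration series therefore yields all three quantities from two
straight-line fits:

1. **Guinier stage** — fit ln I vs Q² per profile → (R_g,obs, I(0)).
2. **Virial stage** — fit I(0)/n vs n → B₂₂ = −a/2b from slope a and
   intercept b.
3. **Interaction stage** — fit R_g,obs² vs −nB₂₂ → slope R_i², intercept
   R_g,0².

For dilute, weakly interacting systems h(r) is the Mayer function
e^(−V(r)/k_BT) − 1, so R_i is directly the root-mean-square range of the
pair potential; for a hard sphere R_i = √(3/5)·σ = 2·R_g,HS exactly, a
closed form the quadrature routines reproduce to 10⁻⁶.

The package is for small-angle X-ray/neutron scattering practitioners who
already run Guinier fits on dilute protein, polymer, or colloid series and
want the concentration-independent size plus an interaction length scale
from the same data.

## Worked example

```sh
python examples/01_simulate_and_analyze.py
```

simulates a six-point lysozyme-like series (2.45–18.56 mg/mL, M_W =
14.3 kDa, R_g,0 = 13 Å, R_i = 38 Å, B₂₂ = −3.8×10⁻²⁰ mL) with 1% counting
noise and inverts it:

```
per-concentration Guinier fits:
  c =   2.45 mg/mL   Rg_obs =  12.88 ± 0.16 Å   I(0) = 0.0517
  ...
  c =  18.56 mg/mL   Rg_obs =  14.68 ± 0.14 Å   I(0) = 0.416

B22   = -4.445e-20 ± 2.5e-21 mL (= -26765 mL/mol)
Ri    = 39.2 ± 2.1 Å   (slope Ri² = 1538 ± 162 Å²)
Rg,0  = 12.72 ± 0.13 Å   (intercept Rg,0² = 161.7 Å²)
Ri/Rg,0 = 3.08
```

R_g,obs rises with concentration because B₂₂ < 0 (net attraction); the
slope of R_g,obs² against −nB₂₂ is the squared interaction radius, and
the intercept extrapolates the radius of gyration to infinite dilution.
The recovered values scatter around the truth at the level the 1% noise
allows (the test suite checks the median over 200 replicates lands within
15% of the true R_i).

Other examples: `02_guinier_single_profile.py` (window sweep and residual
diagnostics on a sphere form factor), `03_potentials.py` (R_i/B₂₂
quadratures and the numeric structure factor vs its low-Q asymptote),
`04_zimm_crosscheck.py` (the interaction-corrected Zimm surface fit as an
independent estimator).

A thin CLI mirrors the library:

```sh
sasri simulate --seed 5 --noise 0.01 --outdir sim/
sasri analyze sim/manifest.txt
sasri potential-ri --form hard_sphere --sigma 34
```

Every command writes a versioned JSON result document and an append-only
run record (parameters, input checksums, package version).

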