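# polyamine-dna

Coarse-grained Monte Carlo modelling of how trivalent polyamines bind
double-stranded DNA, built to explain why **norspermidine (NSPD,
[N-3-N-3-N])** binds DNA more strongly than its natural homologue
**spermidine (SPD, [N-3-N-4-N])** even though both carry +3 charge.
The package is for structural/computational biophysicists who want a
small, fully reproducible model of polyelectrolyte–ligand selectivity,
plus the matching experimental-side estimator: binding constants from
¹H NMR titration slopes.

## The model

One rigid polyamine — a rod of tangent 0.39 nm beads with +1 charges
on the ammonium beads (#1/#5/#10 for SPD, #1/#5/#9 for NSPD) — moves
by Metropolis Monte Carlo around a DNA segment of ten −1 phosphate
sphere pairs (σ = 0.476 nm, 180° apart, 0.34 nm axial rise) on a soft
cylinder of radius R_DNA = 1 nm, inside a periodic cylindrical cell
(H = 3.4 nm, R_cyl = 2.591 or 5.182 nm) at T = 298 K.  Charges
interact through a screened Coulomb potential

    u_ij / k_BT = Γ · z_i z_j · exp(−r/λ_D) / r,

with coupling length Γ = 1.36 nm per ammonium–phosphate pair and Debye
length λ_D = 3.04 nm (10 mM 1:1 buffer) by default.  Beads may
penetrate the DNA envelope against a half-harmonic penalty
½k(R_DNA − ρ)², mimicking the grooves.

Sampled states are reduced to ρ₅(r, cos θ) — the density of the
central ammonium over its radial distance r and the rod's orientation
cosine — and to the conditional free energy F/k_BT = −ln ρ₅.  A sample
is *bound* when all three ammoniums lie within 0.453 nm of a phosphate
simultaneously (the 105° hydrogen-bond contact distance from ionic
radii 0.137/0.258 nm and bond length 0.174 nm).  The binding constant
follows mass action,

    K = ( (N_b/V_b) / (N_f/V_f) ) / [phosphate],

with phase-space volumes V_b, V_f splitting the annulus inside
R_cut = 1.3 nm at |cos θ| = 0.5.

On the experimental side, DNA-bound polyamine protons are
NMR-invisible (T₂ broadening), so the inverse relative ¹H intensity is
linear in DNA concentration with slope K; `titration` fits the
two-regime slopes (K₂ below 0.5 mM DNA, K₁ above) with bootstrap
confidence intervals.

## Worked example

```bash
python examples/03_binding_constants.py
```

prints (seed 1):

```
phase volumes: V_b = 74.5, V_f = 181.8; [phosphate] = 463 mM

SPD: N(binding) = 0.0033, K = 1.753e-05 ± 8.7e-07 mM^-1
NSPD: N(binding) = 0.0058, K = 3.099e-05 ± 1.4e-06 mM^-1

K_NSPD / K_SPD = 1.77 (norspermidine binds about twice as strongly)
```

`N(binding)` is the fraction of Monte Carlo samples with all three
ammoniums in simultaneous phosphate contact; NSPD achieves it about
twice as often as SPD because its symmetric charge spacing fits the
phosphate lattice better, and the K ratio — the model's headline
number — lands near 2.  Absolute K values are orders of magnitude
below the NMR ones by construction: the model neglects counter-ion
release and hydration, so only the species *ratio* is meaningful.

The other examples cover the geometry and hydrogen-bond cutoffs
(`01`), free-energy landscapes and the SPD−NSPD difference map (`02`),
and the titration-slope estimator with bootstrap CIs (`04`).
`polyamine_dna.run_pipeline(RunConfig(), out_dir)` runs everything in
one call and writes CSV/JSON/XYZ artifacts with a manifest.

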