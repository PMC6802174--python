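# Methods

## Model

A single rigid trivalent polyamine interacts with one double-stranded
DNA segment in a cylindrical cell, periodic along the DNA (z) axis.
The reduction to one ligand and one segment corresponds to the dilute
regime — polyamine scarce relative to DNA phosphate — which is also
the regime probed by the high-DNA branch of an NMR titration.

**Polyamine.** A linear chain of tangent spheres of diameter
d = 0.39 nm (methylene and ammonium groups), rigid because of the
molecule's high bending/torsional stiffness at full protonation.  The
three ammoniums carry +1 each: beads #1/#5/#10 of 10 for spermidine
(SPD, [N-3-N-4-N]) and #1/#5/#9 of 9 for norspermidine (NSPD,
[N-3-N-3-N]).  Bead spacing equals the diameter (tangent spheres);
this is the simplest rigid-rod reading of a single bead-size
parameter and gives N–N spacings of 1.56/1.95 nm (SPD) and
1.56/1.56 nm (NSPD) — the asymmetry-vs-symmetry contrast the whole
analysis turns on.

**DNA.** Ten pairs of phosphate spheres (σ = 0.476 nm, charge −1)
at radius R_DNA = 1.0 nm, the two members of a pair 180° apart,
pairs 0.34 nm apart along z, so the segment spans exactly the cell
height H = 3.4 nm.  `twist_per_pair` defaults to 0° (a straight
phosphate ladder); a helical arrangement (36°/pair closes one full
turn over the periodic cell) is available for sensitivity studies but
changes the commensurability between the charge spacings and the
phosphate lattice, and with it the species ordering — see
*Limitations*.  The DNA envelope is *soft*: beads entering ρ < R_DNA
pay ½·soft_k·(R_DNA − ρ)², a stand-in for groove penetration.
Default soft_k = 10 k_BT/nm² lets a bead penetrate ≈ 0.45 nm at a cost
of 1 k_BT, comparable to a groove depth.

**Electrostatics.** Screened Coulomb between charged beads and
phosphates, u/k_BT = Γ z_i z_j e^(−r/λ_D)/r, with minimum-image
axial distances.  Γ (default 1.36 nm) is a coupling *length*: the
magnitude of the contact energy of a unit-charge pair at 1 nm in
k_BT.  λ_D defaults to 3.04 nm (10 mM monovalent buffer at 298 K);
∞ gives bare Coulomb.  Temperature enters only through the k_BT
reduction (T = 298 K).  Bead–phosphate hard cores at (d + σ)/2 =
0.433 nm reject overlapping configurations; the wall at R_cyl rejects
beads outside the cell.  The cell is the normalization volume of the
binding bookkeeping, so the wall applies to all beads.

## Sampling

Metropolis Monte Carlo with symmetric rigid-body proposals: uniform
translations (half-width `max_trans`, initial 0.15 nm) or rotations
about the rod centroid by a uniform angle (±`max_rot`, initial
0.2 rad) around an isotropic random axis; acceptance min(1, e^(−ΔE)).
Step sizes are adapted toward 30–50% acceptance during equilibration
only and frozen for production, so recorded samples satisfy detailed
balance.  Defaults: 10⁵ equilibration and 2×10⁶ production moves,
recording every 10th — a few seconds per run once the numba kernel is
compiled.  A given seed reproduces a trajectory bit for bit; the
kernel's energies are cross-checked in the tests against an
independent numpy implementation of the same Hamiltonian.

Sampler correctness is established on a reduced system (3-bead rod
with charged ends, 2 phosphate pairs) small enough for exhaustive
quadrature: Boltzmann weights are accumulated on a 5-D state grid and
compared with Metropolis marginals bin by bin.  Because the hard core
makes the integrand discontinuous, midpoint nodes converge only
O(h); the oracle therefore uses *stratified* nodes (one uniform draw
per cell, seeded), which are unbiased for discontinuous integrands
and give an honest quadrature error bar from replicates.  With point
charges the hard core is not optional: without excluded volume the
attractive Boltzmann factor diverges at contact and the
configurational integral is undefined.

## Landscapes

Trajectories are reduced to (r, μ): the radial distance of the
central ammonium and the cosine of the rod axis against z.  The
density ρ₅ is a 2-D histogram divided by the phase-space measure
2π·r̄·Δr·Δμ·H per bin (Jacobian correction), so an uncoupled (Γ = 0)
run yields a flat landscape and F/k_BT = −ln ρ₅ is a free energy
rather than a count surface.  Default grid Δr = 0.05 nm over
[0.55, R_cyl], Δμ = 0.1 — about ten radial bins across the bound
shell between the inner annulus edge (0.762 nm) and R_cut.  Empty
bins are NaN: excluded from minima, averages and difference maps,
never imputed.  Normalization uses the in-grid sample count, so the
unit-integral invariant holds exactly on the grid.

## Binding constants

Binding requires all three ammoniums within 0.453 nm (center to
center) of some phosphate simultaneously.  The cutoff derives from a
triangle with its vertex at the hydrogen-bond-accepting oxygen: sides
r_N + d_HB = 0.311 nm and r_P = 0.258 nm with the N-H···O angle
between them give 0.404/0.453/0.569 nm at 90°/105°/180°; 105° is
adopted as the loosest geometry that still counts as a hydrogen bond.
(The vertex-at-oxygen construction is the one that reproduces all
three printed distances; vertex-at-hydrogen does not.)

K = [(N_b/V_b)/(N_f/V_f)]/[phosphate], with the phase volumes

    V_b = [2πH ∫_{R_DNA−σ/2}^{R_cut} r dr]·[2 ∫_{0.5}^{1} dμ ∫_0^{2π} dφ]
    V_f = [same radial factor]·[2 ∫_0^{0.5} dμ ∫ dφ] + 4πH ∫_{R_cut}^{R_cyl} r dr

(R_cut = 1.3 nm, the radius where the landscape's orientation
preference dissolves).  The outer V_f term as written lacks the
orientation measure the bracketed terms carry; it is kept literally by
default (`literal_outer=True`) with a dimensionally consistent
4π-orientation variant switchable — the species ratio is invariant to
the choice because the volumes cancel.  The radial limits are taken in
the positive orientation (inner < outer), the only reading with
positive volume.  [Phosphate] is the overall concentration
2·n_pairs/V_cell (463 mM at R_cyl = 2.591 nm) — the free-phosphate
approximation valid in the dilute-polyamine regime.  Binding is by
the distance criterion alone by default; conditioning additionally on
r < R_cut is available (`require_within_R_cut`) and barely changes
N_b since three-contact poses sit near the envelope anyway.  MC errors
come from 10-block averaging; K = 0 with no bound samples and
undefined (None, never ∞) with no free ones.

## Titration estimator

Bound polyamine is NMR-dark (T₂ broadening), DNA is in excess and
exchange is fast, so the observed intensity tracks the free fraction
1/(1 + K[DNA]) and the inverse relative intensity is 1 + K[DNA].
`fit_two_regime` fits a continuous piecewise-linear model (free
intercept, two slopes) by least squares with the breakpoint fixed at
0.5 mM (profiled over a grid on request); after normalization the
intercept is ≈1 and the slopes are K₂ (low regime) and K₁ (high
regime) directly, in mM⁻¹.  Percentile bootstrap CIs resample points
within each regime (stratified), skipping and counting singular
replicates; n_boot = 1000 is used for reported intervals.

One subtlety: normalizing by the *measured* zero-DNA intensity makes
every point share that measurement's noise, correlating the series in
a way point-resampling cannot represent; bootstrap coverage then dips
a percent or two below its small-sample level.  When a separately
calibrated reference intensity is available it should be supplied via
`invert_normalize(data, I0=...)`; the coverage validation does so.
With 12 points, 2% intensity noise and n_boot = 1000, frozen-seed
coverage of the 95% intervals is 91.6% (K₂) and 90.0% (K₁) — the
expected mild undercoverage of percentile intervals at n = 6 per
regime.

## Synthetic data

The titration generator produces I(c) = I₀/(1 + K₂·min(c, b) +
K₁·max(0, c − b)) with additive Gaussian noise of `noise_sd`·I₀ on
the *intensity* (integration noise in NMR is additive on signal
area, not on its inverse).  Defaults K₂ = 0.36, K₁ = 0.18 mM⁻¹,
b = 0.5 mM, a 0–1.6 mM grid in 0.1 mM steps, 2% noise — a plausible
two-regime series.  It emulates the slope structure only: no
chemical-shift drift, no baseline or phasing artifacts, no
peak-overlap effects, so estimator tests validate slope recovery
under clean two-regime data, not full spectral processing.

## Problem sizes

Tests and the reproduction script use the study conditions directly:
2×10⁶ production moves per run, three seeds per species for the
binding-constant ratio, 2×10⁶-move runs for the Γ sweep (four
couplings × two species × two seeds), ≈9×10⁵-state quadrature
replicates for the sampler oracle, and 500 synthetic replicates for
estimator bias and coverage.  Everything is regenerated at run time;
no stored datasets.

## Limitations

* **Absolute K values are not comparable to experiment.**  Counter-ion
  release entropy, hydration and protonation equilibria are neglected,
  so simulated K is orders of magnitude below titration values; only
  the NSPD/SPD *ratio* (≈1.7 at default conditions, stable across
  λ_D ∈ {1, 3.04, ∞} nm) carries meaning.
* **Three-contact poses are near-axis-parallel in this geometry.**
  With collinear ammoniums (spacings 1.56/1.95 or 1.56/1.56 nm), the
  0.453 nm cutoff and 0.433 nm cores, an exhaustive orientation scan
  over all phosphate triples (any twist, images included) shows
  simultaneous three-contact placements exist only within ~30° of the
  DNA axis.  The free-energy minimum sits at ≈18° tilt.  Tilted
  (~45°) bound poses, as seen in atomistic pictures where grooves and
  flexible side chains break collinearity, are outside this model's
  reach — a consequence of the rigid-rod + smooth-cylinder idealization.
* **Deep-adsorption regime at default coupling.**  At Γ = 1.36 nm and
  λ_D = 3.04 nm, the adsorption well is ≈35 k_BT, so the desorbed
  region (r ≳ 1.6 nm) is thermally unpopulated and the landscape's
  far field carries no statistics; shorter screening lengths shallow
  the well but degrade bound-event statistics instead.  Far-field
  landscape structure (orientation-flattening, the SPD-favored region
  away from the surface) should not be read off this model at default
  coupling.
* **The helical-twist option reverses selectivity.**  With 36°/pair
  the same-azimuth phosphate columns (1.70 nm spacing) match SPD's
  charge pattern better than NSPD's, flipping the K ordering; the
  straight-ladder default is the configuration that expresses the
  commensurability advantage of NSPD's symmetric spacing.
* Single ligand only: no competition, no multi-polyamine correlation,
  no explicit counter-ions, no DNA deformation.
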