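"""Sample one polyamine around DNA and map F(r, cosθ).

Runs Metropolis Monte Carlo for both species at the default coupling
(Γ = 1.36 nm) and reduces the trajectories to the conditional free
energy over the central-ammonium radius r and the orientation cosine.
The minimum marks the preferred bound geometry; ΔF = F_SPD − F_NSPD
shows where norspermidine is favored (positive regions).
"""

import numpy as np

import polyamine_dna as pdna

dna = pdna.build_dna()
cell = pdna.build_cell(2.591, dna)
params = pdna.EnergyParams()  # Γ = 1.36 nm, λ_D = 3.04 nm
r_edges = pdna.default_r_edges(cell)
mu_edges = pdna.default_mu_edges()

grids = {}
for species in ("SPD", "NSPD"):
    pa = pdna.build_polyamine(species)
    traj = pdna.run_mc(pa, dna, cell, params,
                       n_equil=100_000, n_prod=1_000_000, stride=10, seed=1)
    grids[species] = pdna.accumulate_rho5(traj, pa, r_edges, mu_edges, cell)
    r_star, tilt = pdna.locate_minimum(grids[species], r_max=1.3)
    print(
        f"{species}: <E> = {traj.energy.mean():6.1f} k_BT, acceptance "
        f"{traj.acceptance_prod:.0%}; F minimum at r = {r_star:.2f} nm, "
        f"tilt {tilt:.0f} deg from the DNA axis"
    )

dF = pdna.delta_F(grids["SPD"], grids["NSPD"])
rc = dF.r_centers
near = np.nanmean(dF.F_over_kBT[(rc > 0.9) & (rc < 1.1)])
print(f"mean ΔF(SPD−NSPD) near the DNA envelope (r ≈ 1 nm): {near:+.2f} k_BT")
print("positive ΔF near the envelope = norspermidine sits there more often")
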