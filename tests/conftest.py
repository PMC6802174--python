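import dataclasses

import numpy as np
import pytest

import polyamine_dna as pdna


@pytest.fixture(scope="session")
def dna():
    return pdna.build_dna()


@pytest.fixture(scope="session")
def cell(dna):
    return pdna.build_cell(2.591, dna)


@pytest.fixture(scope="session")
def spd():
    return pdna.build_polyamine("SPD")


@pytest.fixture(scope="session")
def nspd():
    return pdna.build_polyamine("NSPD")


@pytest.fixture(scope="session")
def energy_params():
    return pdna.EnergyParams()


@pytest.fixture(scope="session")
def production_runs(dna, cell, energy_params):
    """Study-condition trajectories: both species, Γ = 1.36 nm,
    R_cyl = 2.591 nm, 2×10⁶ production moves, seeds 1–3."""
    runs = {}
    for sp in ("SPD", "NSPD"):
        pa = pdna.build_polyamine(sp)
        for seed in (1, 2, 3):
            runs[(sp, seed)] = pdna.run_mc(
                pa, dna, cell, energy_params,
                n_equil=100_000, n_prod=2_000_000, stride=10, seed=seed,
            )
    return runs


def pooled_trajectory(runs, species):
    """Concatenate the per-seed trajectories of one species."""
    trajs = [runs[(species, s)] for s in (1, 2, 3)]
    return dataclasses.replace(
        trajs[0],
        ref=np.concatenate([t.ref for t in trajs]),
        axis=np.concatenate([t.axis for t in trajs]),
        energy=np.concatenate([t.energy for t in trajs]),
    )


@pytest.fixture(scope="session")
def micro_oracle(dna):
    """Max |z| between MC and stratified-quadrature marginals on the
    micro system (sampler-correctness oracle), plus the grids."""
    spec = pdna.MicroSystemSpec()
    reps = []
    for s in range(4):
        pa, mdna, mcell, states = pdna.generate_micro_system(
            spec, node_rule="stratified", seed=100 + s
        )
        r_edges = np.linspace(0.2, mcell.R_cyl, 9)
        mu_edges = np.linspace(-1, 1, 5)
        reps.append(states.marginal_r_mu(pa, r_edges, mu_edges, mcell))
    reps = np.asarray(reps)
    rho_q = reps.mean(axis=0)
    se_q = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
    traj = pdna.run_mc(pa, mdna, mcell, spec.energy, 50_000, 1_500_000, 5, seed=7)
    grid = pdna.accumulate_rho5(traj, pa, r_edges, mu_edges, mcell)
    se_mc = blocked_rho_se(traj, pa, r_edges, mu_edges, mcell)
    z = (grid.rho5 - rho_q) / np.sqrt(se_mc**2 + se_q**2)
    return {"max_abs_z": float(np.nanmax(np.abs(z))), "rho_mc": grid.rho5,
            "rho_quad": rho_q}


@pytest.fixture(scope="session")
def ideal_gas_landscape():
    """Γ = 0 free-rod landscape over interior bins, with per-bin
    free-energy deviations and their block-noise bounds."""
    pa = pdna.build_polyamine("free", n_beads=3, charged_indices=(1, 3))
    dna = pdna.build_dna()
    cell = pdna.build_cell(2.591, dna)
    p = pdna.EnergyParams(Gamma=0.0, soft_k=0.0, hard_core=False)
    traj = pdna.run_mc(
        pa, dna, cell, p, 20_000, 2_000_000, 10, seed=11,
        max_trans=0.6, max_rot=1.0,
    )
    r_edges = np.arange(0.2, cell.R_cyl - pa.rod_length, 0.2)
    mu_edges = np.linspace(-1, 1, 11)
    grid = pdna.accumulate_rho5(traj, pa, r_edges, mu_edges, cell)
    se_rho = blocked_rho_se(traj, pa, r_edges, mu_edges, cell)
    dev = np.abs(grid.F_over_kBT - np.nanmean(grid.F_over_kBT))
    bound = 4.0 * np.maximum(se_rho / grid.rho5, 1e-3)
    return {"grid": grid, "dev": dev, "bound": bound}


def blocked_rho_se(traj, polyamine, r_edges, mu_edges, cell, n_blocks=16):
    """Block-averaged standard error of the landscape density per bin."""
    r, mu = pdna.reduce_trajectory(traj, polyamine)
    annulus = np.pi * (np.asarray(r_edges[1:]) ** 2 - np.asarray(r_edges[:-1]) ** 2)
    measure = annulus[:, None] * np.diff(mu_edges)[None, :] * cell.H
    rhos = []
    for idx in np.array_split(np.arange(len(r)), n_blocks):
        h, _, _ = np.histogram2d(r[idx], mu[idx], bins=[r_edges, mu_edges])
        rhos.append(h / h.sum() / measure)
    rhos = np.asarray(rhos)
    return rhos.std(axis=0, ddof=1) / np.sqrt(n_blocks)
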