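"""Metropolis Monte Carlo sampling of a rigid polyamine around DNA.

A single rigid polyamine moves in the cylindrical cell by random
rigid-body moves: translations (uniform displacement within a cube of
half-width ``max_trans``) and rotations about the rod centroid (random
axis, angle uniform within ``±max_rot``).  Proposals are symmetric, so
the Metropolis rule ``accept with min(1, e^(−ΔE/k_BT))`` satisfies
detailed balance.  The axial coordinate is wrapped periodically; moves
that place any bead outside the wall at R_cyl (or inside a phosphate
hard core) have infinite energy and are rejected.

Step sizes are tuned toward 30–50% acceptance during equilibration and
then frozen for production, preserving detailed balance where samples
are recorded.  The inner loop is JIT-compiled with numba; recorded
energies are bit-reproducible for a given seed and are cross-checked in
the test suite against the plain-numpy energy reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .energy import Configuration, EnergyParams, total_energy
from .geometry import DNAModel, PolyamineModel, SimulationCell

__all__ = ["Trajectory", "run_mc", "metropolis_acceptance", "GeometryError"]


class GeometryError(ValueError):
    """No valid starting configuration exists in the cell."""


def metropolis_acceptance(delta_e: float) -> float:
    """Acceptance probability min(1, e^(−ΔE)) for a symmetric proposal."""
    return 1.0 if delta_e <= 0 else math.exp(-delta_e)


@dataclass
class Trajectory:
    """Strided production samples of the rigid-body state.

    ``ref`` holds the position of bead #1 (z wrapped into [0, H)),
    ``axis`` the unit rod direction (bead #1 → last bead) and ``energy``
    the total reduced energy at the sampled step.
    """

    species: str
    seed: int
    stride: int
    n_equil: int
    n_prod: int
    ref: np.ndarray  # (M, 3)
    axis: np.ndarray  # (M, 3)
    energy: np.ndarray  # (M,)
    acceptance_equil: float
    acceptance_prod: float
    max_trans: float  # frozen production step sizes
    max_rot: float

    def __len__(self) -> int:
        return self.ref.shape[0]

    def configurations(self):
        """Iterate samples as :class:`Configuration` objects."""
        for p, u in zip(self.ref, self.axis):
            yield Configuration(ref_position=p.copy(), orientation=u.copy())

    def bead_positions(self, polyamine: PolyamineModel) -> np.ndarray:
        """Lab-frame bead centers for every sample, (M, n_beads, 3)."""
        return (
            self.ref[:, None, :]
            + polyamine.bead_offsets[None, :, None] * self.axis[:, None, :]
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(len(self)) * self.stride,
                "x": self.ref[:, 0],
                "y": self.ref[:, 1],
                "z": self.ref[:, 2],
                "ux": self.axis[:, 0],
                "uy": self.axis[:, 1],
                "uz": self.axis[:, 2],
                "energy_kBT": self.energy,
            }
        )


@njit(cache=True)
def _energy_kernel(
    ref, u, offsets, charges, phos, H, R_cyl, R_DNA, contact2, gamma, inv_lam, soft_k, hard_core
):
    e = 0.0
    n = offsets.shape[0]
    m = phos.shape[0]
    for i in range(n):
        px = ref[0] + offsets[i] * u[0]
        py = ref[1] + offsets[i] * u[1]
        pz = ref[2] + offsets[i] * u[2]
        rho = math.hypot(px, py)
        if rho > R_cyl:
            return np.inf
        if rho < R_DNA:
            d = R_DNA - rho
            e += 0.5 * soft_k * d * d
        qi = charges[i]
        for j in range(m):
            dx = px - phos[j, 0]
            dy = py - phos[j, 1]
            dz = pz - phos[j, 2]
            dz -= H * round(dz / H)
            r2 = dx * dx + dy * dy + dz * dz
            if hard_core and r2 < contact2:
                return np.inf
            if qi != 0.0:
                r = math.sqrt(r2)
                # phosphates carry -1
                e += gamma * qi * (-1.0) * math.exp(-r * inv_lam) / r
    return e


@njit(cache=True)
def _mc_kernel(
    ref0,
    u0,
    offsets,
    charges,
    phos,
    H,
    R_cyl,
    R_DNA,
    contact2,
    gamma,
    inv_lam,
    soft_k,
    hard_core,
    n_equil,
    n_prod,
    stride,
    seed,
    max_trans0,
    max_rot0,
    tune,
):
    np.random.seed(seed)
    ref = ref0.copy()
    u = u0.copy()
    half_len = 0.5 * offsets[offsets.shape[0] - 1]
    e = _energy_kernel(
        ref, u, offsets, charges, phos, H, R_cyl, R_DNA, contact2, gamma, inv_lam, soft_k, hard_core
    )
    max_trans = max_trans0
    max_rot = max_rot0

    n_samples = n_prod // stride
    out_ref = np.empty((n_samples, 3))
    out_axis = np.empty((n_samples, 3))
    out_e = np.empty(n_samples)

    acc_equil = 0
    acc_prod = 0
    tune_window = 2000
    tune_acc = 0

    new_ref = np.empty(3)
    new_u = np.empty(3)
    for step in range(n_equil + n_prod):
        if np.random.random() < 0.5:
            # translation
            for k in range(3):
                new_ref[k] = ref[k] + max_trans * (2.0 * np.random.random() - 1.0)
            new_u[0] = u[0]
            new_u[1] = u[1]
            new_u[2] = u[2]
        else:
            # rotation about the rod centroid: random axis, uniform angle
            ax = np.random.standard_normal()
            ay = np.random.standard_normal()
            az = np.random.standard_normal()
            an = math.sqrt(ax * ax + ay * ay + az * az)
            if an < 1e-12:
                ax, ay, az, an = 1.0, 0.0, 0.0, 1.0
            ax /= an
            ay /= an
            az /= an
            ang = max_rot * (2.0 * np.random.random() - 1.0)
            c = math.cos(ang)
            s = math.sin(ang)
            # Rodrigues rotation of u
            dot = ax * u[0] + ay * u[1] + az * u[2]
            cx = ay * u[2] - az * u[1]
            cy = az * u[0] - ax * u[2]
            cz = ax * u[1] - ay * u[0]
            new_u[0] = u[0] * c + cx * s + ax * dot * (1.0 - c)
            new_u[1] = u[1] * c + cy * s + ay * dot * (1.0 - c)
            new_u[2] = u[2] * c + cz * s + az * dot * (1.0 - c)
            un = math.sqrt(new_u[0] ** 2 + new_u[1] ** 2 + new_u[2] ** 2)
            new_u[0] /= un
            new_u[1] /= un
            new_u[2] /= un
            for k in range(3):
                cen = ref[k] + half_len * u[k]
                new_ref[k] = cen - half_len * new_u[k]
        new_ref[2] -= H * math.floor(new_ref[2] / H)

        e_new = _energy_kernel(
            new_ref, new_u, offsets, charges, phos, H, R_cyl, R_DNA, contact2,
            gamma, inv_lam, soft_k, hard_core,
        )
        accept = False
        if e_new <= e:
            accept = True
        elif e_new < np.inf:
            if np.random.random() < math.exp(-(e_new - e)):
                accept = True
        if accept:
            ref[0] = new_ref[0]
            ref[1] = new_ref[1]
            ref[2] = new_ref[2]
            u[0] = new_u[0]
            u[1] = new_u[1]
            u[2] = new_u[2]
            e = e_new

        if step < n_equil:
            if accept:
                acc_equil += 1
                tune_acc += 1
            if tune and (step + 1) % tune_window == 0:
                frac = tune_acc / tune_window
                if frac < 0.30:
                    max_trans = max(max_trans / 1.1, 1e-3)
                    max_rot = max(max_rot / 1.1, 1e-3)
                elif frac > 0.50:
                    max_trans = min(max_trans * 1.1, R_cyl)
                    max_rot = min(max_rot * 1.1, math.pi)
                tune_acc = 0
        else:
            if accept:
                acc_prod += 1
            prod_step = step - n_equil + 1
            if prod_step % stride == 0:
                idx = prod_step // stride - 1
                out_ref[idx, 0] = ref[0]
                out_ref[idx, 1] = ref[1]
                out_ref[idx, 2] = ref[2]
                out_axis[idx, 0] = u[0]
                out_axis[idx, 1] = u[1]
                out_axis[idx, 2] = u[2]
                out_e[idx] = e

    a_eq = acc_equil / n_equil if n_equil > 0 else 0.0
    a_pr = acc_prod / n_prod if n_prod > 0 else 0.0
    return out_ref, out_axis, out_e, a_eq, a_pr, max_trans, max_rot


def _initial_configuration(polyamine, dna, cell, params) -> Configuration:
    """First rejection-free placement on a coarse (radius, orientation) scan."""
    axes = [
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
        np.array([math.sqrt(0.5), 0.0, math.sqrt(0.5)]),
    ]
    radii = np.linspace(dna.R_DNA + 0.3, cell.R_cyl - 0.05, 12)
    for r in radii:
        for u in axes:
            cfg = Configuration(
                ref_position=np.array([r, 0.0, 0.5 * cell.H]), orientation=u
            )
            if math.isfinite(total_energy(cfg, polyamine, dna, params, cell)):
                return cfg
    raise GeometryError(
        f"no valid starting configuration for a {polyamine.rod_length:.2f} nm rod "
        f"in a cell of radius {cell.R_cyl} nm"
    )


def run_mc(
    polyamine: PolyamineModel,
    dna: DNAModel,
    cell: SimulationCell,
    params: EnergyParams,
    n_equil: int = 100_000,
    n_prod: int = 2_000_000,
    stride: int = 10,
    seed: int = 0,
    max_trans: float = 0.15,
    max_rot: float = 0.2,
    tune: bool = True,
) -> Trajectory:
    """Sample the polyamine's rigid-body states by Metropolis Monte Carlo.

    Returns every ``stride``-th production sample.  Identical inputs and
    seed give an identical trajectory.
    """
    if n_equil < 0 or n_prod <= 0 or stride <= 0:
        raise ValueError("counts must be positive (n_equil may be 0)")
    start = _initial_configuration(polyamine, dna, cell, params)
    inv_lam = 0.0 if math.isinf(params.debye_length) else 1.0 / params.debye_length
    contact = 0.5 * (polyamine.bead_diameter + dna.phosphate_diameter)
    out_ref, out_axis, out_e, a_eq, a_pr, ft, fr = _mc_kernel(
        start.ref_position,
        start.orientation,
        polyamine.bead_offsets,
        polyamine.charges,
        dna.phosphate_positions,
        cell.H,
        cell.R_cyl,
        dna.R_DNA,
        contact * contact,
        params.Gamma,
        inv_lam,
        params.soft_k,
        params.hard_core,
        n_equil,
        n_prod,
        stride,
        seed,
        max_trans,
        max_rot,
        tune,
    )
    return Trajectory(
        species=polyamine.species_name,
        seed=seed,
        stride=stride,
        n_equil=n_equil,
        n_prod=n_prod,
        ref=out_ref,
        axis=out_axis,
        energy=out_e,
        acceptance_equil=a_eq,
        acceptance_prod=a_pr,
        max_trans=ft,
        max_rot=fr,
    )
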