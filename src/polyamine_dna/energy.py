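"""Screened-Coulomb + soft-cylinder energy of one rigid polyamine near DNA.

The interaction between an ammonium bead (charge ``z_i``) and a phosphate
sphere (charge ``z_j``) separated by ``r`` is a screened Coulomb
(Debye-Hückel) potential, already reduced by k_BT at T = 298 K::

    u_ij / k_BT = Γ · z_i · z_j · exp(−r / λ_D) / r

Γ is a coupling length (k_BT·nm per unit-charge pair; default 1.36 nm)
and λ_D the Debye screening length (default 3.04 nm, a 10 mM 1:1 buffer
at 298 K; ``inf`` gives the unscreened Coulomb form).  Temperature enters
only through this reduction.

The DNA envelope at R_DNA is *soft*: a bead at axial radius ρ < R_DNA
pays a half-harmonic penalty ½·k·(R_DNA − ρ)², mimicking partial
penetration into the grooves.  Bead–phosphate hard cores at
(d + σ)/2 and the outer cylindrical wall at R_cyl are rejecting
(infinite energy).  Axial distances use the minimum-image convention.

This module is the plain-numpy reference; the Monte Carlo kernel in
:mod:`polyamine_dna.mc` re-implements the same energy for speed and is
tested against this one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import DNAModel, PolyamineModel, SimulationCell

__all__ = ["EnergyParams", "Configuration", "pair_energy", "total_energy"]


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the reduced (k_BT-scaled) energy function."""

    Gamma: float = 1.36  # k_BT·nm per unit-charge pair
    debye_length: float = 3.04  # nm; inf = unscreened
    soft_k: float = 10.0  # k_BT/nm², half-harmonic DNA-envelope stiffness
    hard_core: bool = True  # bead-phosphate contact exclusion

    def __post_init__(self):
        if self.Gamma < 0:
            raise ValueError("Gamma must be >= 0")
        if not self.debye_length > 0:
            raise ValueError("debye_length must be positive (inf allowed)")
        if self.soft_k < 0:
            raise ValueError("soft_k must be >= 0")


@dataclass
class Configuration:
    """Rigid-body state: position of bead #1 and the rod axis direction."""

    ref_position: np.ndarray  # (3,) nm
    orientation: np.ndarray  # (3,) unit vector, bead #1 -> last bead

    def __post_init__(self):
        self.ref_position = np.asarray(self.ref_position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"orientation must be a unit vector (|u| = {n:.3g})")

    def bead_positions(self, polyamine: PolyamineModel) -> np.ndarray:
        """Lab-frame bead centers, (n_beads, 3)."""
        return self.ref_position + np.outer(
            polyamine.bead_offsets, self.orientation
        )

    @property
    def cos_tilt(self) -> float:
        """cos θ between the rod axis (bead #1 → #5 direction) and the DNA axis."""
        return float(self.orientation[2])


def pair_energy(r, z_i, z_j, params: EnergyParams):
    """Screened-Coulomb energy (k_BT) of one charge pair at separation r (nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive (overlap is handled "
                         "by the hard core, not the Coulomb term)")
    screen = np.exp(-r / params.debye_length) if math.isfinite(params.debye_length) else 1.0
    out = params.Gamma * z_i * z_j * screen / r
    return float(out) if out.ndim == 0 else out


def total_energy(
    config: Configuration,
    polyamine: PolyamineModel,
    dna: DNAModel,
    params: EnergyParams,
    cell: SimulationCell,
) -> float:
    """Total reduced energy of a configuration; ``inf`` if rejected.

    Sum of screened-Coulomb pair energies over all (charged bead,
    phosphate) pairs with minimum-image axial distance, plus the
    soft-envelope penalty for every bead inside R_DNA.  Infinite if any
    bead lies outside the cell wall or (with ``hard_core``) overlaps a
    phosphate core.
    """
    beads = config.bead_positions(polyamine)
    rho = np.hypot(beads[:, 0], beads[:, 1])
    if np.any(rho > cell.R_cyl):
        return math.inf

    phos = dna.phosphate_positions
    dxy = beads[:, None, :2] - phos[None, :, :2]
    dz = cell.min_image_dz(beads[:, None, 2] - phos[None, :, 2])
    r = np.sqrt(dxy[..., 0] ** 2 + dxy[..., 1] ** 2 + dz**2)

    contact = 0.5 * (polyamine.bead_diameter + dna.phosphate_diameter)
    if params.hard_core and np.any(r < contact):
        return math.inf

    e = 0.0
    q = polyamine.charges
    charged = q != 0
    if np.any(charged):
        # phosphates all carry -1
        e += float(
            np.sum(pair_energy(r[charged], q[charged, None], -1.0, params))
        )
    inside = rho < dna.R_DNA
    if np.any(inside):
        e += 0.5 * params.soft_k * float(np.sum((dna.R_DNA - rho[inside]) ** 2))
    return e
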