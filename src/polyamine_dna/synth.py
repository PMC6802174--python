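"""Synthetic inputs: NMR titration series and micro-system oracles.

Everything the analysis stages consume can be generated here, seeded
and parameter-for-parameter explicit:

* :func:`generate_titration` emulates the structure of a two-regime
  polyamine/DNA NMR titration — inverse relative intensity rising
  linearly with DNA concentration with a slope change at 0.5 mM — with
  additive Gaussian noise on the signal intensity (integration noise in
  NMR is additive on signal area, not on its inverse).

* :func:`generate_micro_system` builds a reduced polyamine/DNA system
  small enough for exhaustive Boltzmann quadrature over a discretized
  (position × orientation) state grid.  The resulting state table is
  the brute-force oracle against which the Metropolis sampler and the
  landscape estimator are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .energy import EnergyParams
from .geometry import (
    DNAModel,
    PolyamineModel,
    SimulationCell,
    build_cell,
    build_dna,
    build_polyamine,
)
from .mc import _energy_kernel
from .titration import TitrationDataset

__all__ = [
    "TitrationGeneratorSpec",
    "generate_titration",
    "MicroSystemSpec",
    "QuadratureStates",
    "generate_micro_system",
]


@dataclass(frozen=True)
class TitrationGeneratorSpec:
    """Ground truth for a synthetic titration series.

    Defaults mirror the experimentally reported slopes: K₂ = 0.36 mM⁻¹
    below the 0.5 mM breakpoint and K₁ = 0.18 mM⁻¹ above it, with a
    17-point 0–1.6 mM concentration grid spanning both regimes.
    """

    K2: float = 0.36  # mM⁻¹, low-concentration slope
    K1: float = 0.18  # mM⁻¹, high-concentration slope
    breakpoint: float = 0.5  # mM
    I0: float = 1000.0  # a.u., zero-DNA intensity
    conc_grid: tuple = tuple(np.round(np.arange(0, 1.601, 0.1), 10))
    noise_sd: float = 0.02  # fraction of I0, additive on intensity
    seed: int = 0

    def noiseless_intensity(self, conc) -> np.ndarray:
        """I(c) = I₀ / (1 + K₂·min(c, b) + K₁·max(0, c − b))."""
        c = np.asarray(conc, dtype=float)
        slope = self.K2 * np.minimum(c, self.breakpoint) + self.K1 * np.maximum(
            c - self.breakpoint, 0.0
        )
        return self.I0 / (1.0 + slope)


def generate_titration(spec: TitrationGeneratorSpec) -> TitrationDataset:
    """Simulate one titration series under ``spec`` (seeded)."""
    conc = np.asarray(spec.conc_grid, dtype=float)
    if not (np.any(conc < spec.breakpoint) and np.any(conc > spec.breakpoint)):
        raise ValueError("concentration grid must span both regimes")
    if spec.noise_sd < 0 or spec.I0 <= 0:
        raise ValueError("noise_sd must be >= 0 and I0 > 0")
    rng = np.random.default_rng(spec.seed)
    intensity = spec.noiseless_intensity(conc)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd * spec.I0, conc.shape)
    if np.any(intensity <= 0):
        raise ValueError("noise level produced non-positive intensities")
    return TitrationDataset(dna_conc=conc, intensity=intensity)


@dataclass(frozen=True)
class MicroSystemSpec:
    """A reduced system plus the resolution of its quadrature grid.

    The defaults give a 3-bead rod with two charged ends near a 2-pair
    DNA stub.  The hard core must stay on: with point charges and no
    excluded volume the attractive Boltzmann weight diverges at contact
    and the configurational integral is ill-defined.
    """

    n_beads: int = 3
    charged_indices: tuple = (1, 3)
    bead_diameter: float = 0.39
    n_pairs: int = 2
    R_cyl: float = 1.8
    energy: EnergyParams = field(
        default_factory=lambda: EnergyParams(
            Gamma=0.5, debye_length=3.04, soft_k=2.0, hard_core=True
        )
    )
    # state-grid resolution: radius, azimuth, height, cos(tilt), axis azimuth
    n_r: int = 36
    n_phi: int = 12
    n_z: int = 8
    n_mu: int = 20
    n_phiu: int = 12
    max_states: int = 5_000_000

    @property
    def n_states(self) -> int:
        return self.n_r * self.n_phi * self.n_z * self.n_mu * self.n_phiu


@njit(cache=True)
def _quadrature_energies(
    r_n, phi_n, z_n, mu_n, phiu_n, offsets, charges, phos,
    H, R_cyl, R_DNA, contact2, gamma, inv_lam, soft_k, hard_core,
):
    """Energies at explicit state nodes; weight element is r·exp(−E)."""
    n = r_n.shape[0]
    ref = np.empty((n, 3))
    axis = np.empty((n, 3))
    energy = np.empty(n)
    measure = np.empty(n)
    for k in range(n):
        r = r_n[k]
        ref[k, 0] = r * math.cos(phi_n[k])
        ref[k, 1] = r * math.sin(phi_n[k])
        ref[k, 2] = z_n[k]
        mu = mu_n[k]
        smu = math.sqrt(max(1.0 - mu * mu, 0.0))
        axis[k, 0] = smu * math.cos(phiu_n[k])
        axis[k, 1] = smu * math.sin(phiu_n[k])
        axis[k, 2] = mu
        energy[k] = _energy_kernel(
            ref[k], axis[k], offsets, charges, phos,
            H, R_cyl, R_DNA, contact2, gamma, inv_lam, soft_k, hard_core,
        )
        measure[k] = r  # radial Jacobian; uniform cell volumes cancel
    return ref, axis, energy, measure


@dataclass
class QuadratureStates:
    """Exhaustive discretized state list with Boltzmann weights.

    ``weight = measure · exp(−E)`` where the measure carries the radial
    Jacobian of the reference-bead position (angular and axial elements
    are uniform and cancel in normalized marginals).
    """

    ref: np.ndarray  # (n, 3) reference-bead positions
    axis: np.ndarray  # (n, 3) rod directions
    energy: np.ndarray  # (n,) k_BT; inf on rejected states
    measure: np.ndarray  # (n,) positional Jacobian element

    @property
    def weights(self) -> np.ndarray:
        w = np.where(np.isfinite(self.energy), np.exp(-self.energy), 0.0)
        return self.measure * w

    @property
    def partition_value(self) -> float:
        return float(self.weights.sum())

    def marginal_r_mu(
        self,
        polyamine: PolyamineModel,
        r_edges: np.ndarray,
        mu_edges: np.ndarray,
        cell: SimulationCell,
    ) -> np.ndarray:
        """Quadrature density on the same (r, μ) grid and normalization
        as the trajectory-based landscape estimator."""
        idx = polyamine.charged_indices
        mid = idx[len(idx) // 2] - 1
        off = polyamine.bead_offsets[mid]
        pos = self.ref[:, :2] + off * self.axis[:, :2]
        r = np.hypot(pos[:, 0], pos[:, 1])
        mu = self.axis[:, 2]
        w = self.weights
        hist, _, _ = np.histogram2d(r, mu, bins=[r_edges, mu_edges], weights=w)
        annulus = np.pi * (np.asarray(r_edges[1:]) ** 2 - np.asarray(r_edges[:-1]) ** 2)
        meas = annulus[:, None] * np.diff(mu_edges)[None, :] * cell.H
        return hist / hist.sum() / meas


def generate_micro_system(
    spec: MicroSystemSpec = MicroSystemSpec(),
    node_rule: str = "midpoint",
    seed: int = 0,
):
    """Build the reduced system and its quadrature oracle.

    Returns ``(polyamine, dna, cell, states)``; raises if the grid
    exceeds the state cap.

    ``node_rule`` places one node per grid cell: ``"midpoint"`` (cell
    centers; deterministic but O(h)-biased at the hard-core and wall
    boundaries) or ``"stratified"`` (uniform within each cell, seeded;
    unbiased for the discontinuous integrand, so replicates over seeds
    give an honest quadrature error bar).
    """
    if spec.n_states > spec.max_states:
        raise ValueError(
            f"quadrature grid has {spec.n_states} states, over the cap "
            f"{spec.max_states}"
        )
    if node_rule not in ("midpoint", "stratified"):
        raise ValueError(f"unknown node rule {node_rule!r}")
    pa = build_polyamine(
        "micro",
        d=spec.bead_diameter,
        n_beads=spec.n_beads,
        charged_indices=spec.charged_indices,
    )
    dna = build_dna(n_pairs=spec.n_pairs)
    cell = build_cell(spec.R_cyl, dna)
    p = spec.energy
    inv_lam = 0.0 if math.isinf(p.debye_length) else 1.0 / p.debye_length
    contact = 0.5 * (pa.bead_diameter + dna.phosphate_diameter)
    dims = (spec.n_r, spec.n_phi, spec.n_z, spec.n_mu, spec.n_phiu)
    idx = np.indices(dims).reshape(5, -1).astype(float)
    if node_rule == "midpoint":
        frac = idx + 0.5
    else:
        rng = np.random.default_rng(seed)
        frac = idx + rng.random(idx.shape)
    r_n = frac[0] * (cell.R_cyl / spec.n_r)
    phi_n = frac[1] * (2 * math.pi / spec.n_phi)
    z_n = frac[2] * (cell.H / spec.n_z)
    mu_n = -1.0 + frac[3] * (2.0 / spec.n_mu)
    phiu_n = frac[4] * (2 * math.pi / spec.n_phiu)
    ref, axis, energy, measure = _quadrature_energies(
        r_n, phi_n, z_n, mu_n, phiu_n,
        pa.bead_offsets, pa.charges, dna.phosphate_positions,
        cell.H, cell.R_cyl, dna.R_DNA, contact * contact,
        p.Gamma, inv_lam, p.soft_k, p.hard_core,
    )
    return pa, dna, cell, QuadratureStates(ref, axis, energy, measure)
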