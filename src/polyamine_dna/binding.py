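"""Bound-state detection and binding-constant estimation.

A polyamine sample is *bound* when all three of its ammonium beads lie
simultaneously within the binding cutoff (0.453 nm, the 105°
hydrogen-bond contact distance) of at least one phosphate sphere,
center-to-center with the minimum-image convention along the axis.

The binding constant follows the mass-action bookkeeping

    K = ([PA−P] / [PA]) / [Phosphate],
    [PA−P]/[PA] = (N(binding)/V_b) / (N(nonbinding)/V_f),

where N(binding) is the fraction of bound MC samples
(N(binding) + N(nonbinding) = 1 exactly) and V_b, V_f are the
phase-space volumes assigned to bound and free states: an annulus from
R_DNA − σ/2 out to R_cut = 1.3 nm with orientation cosine |μ| in
[0.5, 1] for the bound volume, the complementary |μ| slab of the same
annulus plus the outer region out to the cell wall for the free volume.
The free phosphate concentration is approximated by the overall
phosphate concentration in the cell (the single-polyamine, low
polyamine-to-phosphate regime).

The printed form of the outer free-volume term (``4πH ∫ r dr``) lacks
the orientation measure that the annulus terms carry; it is the default
(``literal_outer=True``), with a dimensionally consistent variant
(``[2πH ∫ r dr]·[4π]``) switchable.  The NSPD/SPD binding-constant
ratio is invariant to this choice since the volumes cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import Configuration
from .geometry import DNAModel, PolyamineModel, SimulationCell
from .mc import Trajectory

__all__ = [
    "BindingParams",
    "BindingResult",
    "NM3_TO_MM",
    "is_bound",
    "bound_mask",
    "phase_volumes",
    "phosphate_concentration_mM",
    "binding_K",
    "gamma_sweep",
]

#: 1 nm⁻³ in mM (1 / N_A per nm³ in litres)
NM3_TO_MM = 1.6605390671738466e3


@dataclass(frozen=True)
class BindingParams:
    """Geometric parameters of the bound/free bookkeeping."""

    bind_cutoff: float = 0.453  # nm, ammonium-N to phosphate-P centers
    R_cut: float = 1.3  # nm, bound/free radial boundary
    mu_split: float = 0.5  # |cosθ| boundary of the bound orientation slab
    literal_outer: bool = True  # printed (4πH∫r dr) outer free-volume term
    require_within_R_cut: bool = False  # also condition bound states on r₅ < R_cut

    def __post_init__(self):
        if self.bind_cutoff <= 0 or self.R_cut <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 <= self.mu_split <= 1:
            raise ValueError("mu_split must lie in [0, 1]")


@dataclass
class BindingResult:
    """Binding constant of one species at one (Γ, R_cyl) condition."""

    species: str
    N_binding: float
    N_nonbinding: float
    V_b: float
    V_f: float
    phosphate_mM: float
    K_per_mM: float | None  # None when unmeasurable (no free samples)
    K_stderr: float | None  # block-averaged MC standard error
    n_samples: int

    @property
    def concentration_ratio(self) -> float | None:
        """[PA−P]/[PA] = (N_b/V_b)/(N_f/V_f)."""
        if self.N_nonbinding == 0:
            return None
        return (self.N_binding / self.V_b) / (self.N_nonbinding / self.V_f)


def _min_distances(amm_xyz: np.ndarray, dna: DNAModel, cell: SimulationCell):
    """Min over phosphates of the minimum-image distance, per ammonium."""
    ph = dna.phosphate_positions
    dx = amm_xyz[..., None, 0] - ph[:, 0]
    dy = amm_xyz[..., None, 1] - ph[:, 1]
    dz = cell.min_image_dz(amm_xyz[..., None, 2] - ph[:, 2])
    return np.sqrt(dx * dx + dy * dy + dz * dz).min(axis=-1)


def is_bound(
    config: Configuration,
    polyamine: PolyamineModel,
    dna: DNAModel,
    cell: SimulationCell,
    cutoff: float = 0.453,
) -> bool:
    """True iff every ammonium is within ``cutoff`` of some phosphate."""
    beads = config.bead_positions(polyamine)
    amm = beads[[i - 1 for i in polyamine.charged_indices]]
    return bool(np.all(_min_distances(amm, dna, cell) < cutoff))


def bound_mask(
    traj: Trajectory,
    polyamine: PolyamineModel,
    dna: DNAModel,
    cell: SimulationCell,
    cutoff: float = 0.453,
) -> np.ndarray:
    """Vectorized :func:`is_bound` over a trajectory, (M,) boolean."""
    idx = np.array([i - 1 for i in polyamine.charged_indices])
    amm = (
        traj.ref[:, None, :]
        + polyamine.bead_offsets[idx][None, :, None] * traj.axis[:, None, :]
    )
    return np.all(_min_distances(amm, dna, cell) < cutoff, axis=1)


def phase_volumes(
    cell: SimulationCell,
    dna: DNAModel,
    params: BindingParams = BindingParams(),
) -> tuple[float, float]:
    """Bound and free phase-space volumes (V_b, V_f).

    Both share the annular radial factor 2πH ∫ r dr over
    (R_DNA − σ/2, R_cut); the orientation measure 2 ∫ dμ ∫ dφ splits
    it at |μ| = 0.5 into the bound ([0.5, 1]) and free ([0, 0.5])
    slabs.  The free volume adds the outer annulus (R_cut, R_cyl) —
    literally ``4πH ∫ r dr`` by default, or with the full 4π
    orientation measure if ``literal_outer`` is off.
    """
    r_in = dna.R_DNA - dna.phosphate_diameter / 2.0
    if not (r_in < params.R_cut < cell.R_cyl):
        raise ValueError(
            f"need R_DNA - sigma/2 < R_cut < R_cyl, got {r_in:.3f}, "
            f"{params.R_cut}, {cell.R_cyl}"
        )
    radial_in = math.pi * cell.H * (params.R_cut**2 - r_in**2)  # 2πH ∫ r dr
    mu_b = 2.0 * (1.0 - params.mu_split) * 2.0 * math.pi  # 2 ∫_{0.5}^{1} dμ ∫ dφ
    mu_f = 2.0 * params.mu_split * 2.0 * math.pi
    V_b = radial_in * mu_b
    radial_out = math.pi * cell.H * (cell.R_cyl**2 - params.R_cut**2)
    if params.literal_outer:
        outer = 2.0 * radial_out  # the printed 4πH ∫ r dr
    else:
        outer = radial_out * 4.0 * math.pi
    V_f = radial_in * mu_f + outer
    return V_b, V_f


def phosphate_concentration_mM(dna: DNAModel, cell: SimulationCell) -> float:
    """Overall phosphate concentration 2·n_pairs / V_cell, in mM."""
    return dna.n_phosphates / cell.volume * NM3_TO_MM


def binding_K(
    traj: Trajectory,
    polyamine: PolyamineModel,
    dna: DNAModel,
    cell: SimulationCell,
    params: BindingParams = BindingParams(),
    n_blocks: int = 10,
) -> BindingResult:
    """Binding constant (mM⁻¹) from a trajectory, with block-averaged error.

    ``K = None`` when every sample is bound (the free fraction is
    unmeasurable); ``K = 0`` when no sample is bound.
    """
    mask = bound_mask(traj, polyamine, dna, cell, params.bind_cutoff)
    if params.require_within_R_cut:
        from .landscape import reduce_trajectory

        r5, _ = reduce_trajectory(traj, polyamine)
        mask = mask & (r5 < params.R_cut)
    n_b = float(mask.mean())
    n_f = 1.0 - n_b
    V_b, V_f = phase_volumes(cell, dna, params)
    conc = phosphate_concentration_mM(dna, cell)

    def k_of(nb: float) -> float | None:
        if nb >= 1.0:
            return None
        return (nb / V_b) / ((1.0 - nb) / V_f) / conc

    K = k_of(n_b)
    stderr = None
    if K is not None and len(mask) >= n_blocks:
        blocks = np.array_split(mask, n_blocks)
        ks = [k_of(float(b.mean())) for b in blocks]
        ks = np.array([k for k in ks if k is not None], dtype=float)
        if len(ks) >= 2:
            stderr = float(ks.std(ddof=1) / math.sqrt(len(ks)))
    return BindingResult(
        species=traj.species,
        N_binding=n_b,
        N_nonbinding=n_f,
        V_b=V_b,
        V_f=V_f,
        phosphate_mM=conc,
        K_per_mM=K,
        K_stderr=stderr,
        n_samples=len(mask),
    )


def gamma_sweep(
    species: list[str],
    gamma_grid,
    R_cyl_list,
    seeds,
    *,
    base_energy=None,
    binding_params: BindingParams = BindingParams(),
    n_equil: int = 100_000,
    n_prod: int = 2_000_000,
    stride: int = 10,
    twist_per_pair: float = 0.0,
):
    """Binding constants over a (species × Γ × R_cyl × seed) grid.

    Runs one MC simulation per combination and returns a long-format
    DataFrame (species, gamma, rcyl, seed, N_binding, K, stderr)
    mirroring the K-versus-Γ presentation of the model study.
    """
    import pandas as pd
    from dataclasses import replace

    from .energy import EnergyParams
    from .geometry import build_cell, build_dna, build_polyamine
    from .mc import run_mc

    if len(list(gamma_grid)) == 0 or not species or len(list(R_cyl_list)) == 0:
        raise ValueError("species, gamma_grid and R_cyl_list must be non-empty")
    base = base_energy if base_energy is not None else EnergyParams()
    rows = []
    dna = build_dna(twist_per_pair=twist_per_pair)
    for rcyl in R_cyl_list:
        cell = build_cell(rcyl, dna)
        for sp in species:
            pa = build_polyamine(sp)
            for gamma in gamma_grid:
                p = replace(base, Gamma=float(gamma))
                for seed in seeds:
                    traj = run_mc(
                        pa, dna, cell, p,
                        n_equil=n_equil, n_prod=n_prod, stride=stride, seed=int(seed),
                    )
                    res = binding_K(traj, pa, dna, cell, binding_params)
                    rows.append(
                        {
                            "species": sp,
                            "gamma": float(gamma),
                            "rcyl": float(rcyl),
                            "seed": int(seed),
                            "N_binding": res.N_binding,
                            "K_per_mM": res.K_per_mM,
                            "K_stderr": res.K_stderr,
                        }
                    )
    return pd.DataFrame(rows)
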