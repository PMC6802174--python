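"""Conditional free-energy landscapes F(r, cosθ) from MC trajectories.

The sampled rigid-body states are reduced to two collective variables:
``r``, the radial distance of the central (#5) ammonium from the DNA
axis, and ``μ = cosθ``, the orientation cosine of the #1 → #5 ammonium
vector relative to the axis.  Their two-variable density ρ₅(r, μ) is
histogram-estimated with a phase-space (Jacobian) normalization — each
bin's count is divided by its measure 2π·r̄·Δr·Δμ·H — so that an
ideal-gas (Γ = 0) run gives a flat landscape and

    F(r, μ) / k_BT = −ln ρ₅(r, μ)

is a conditional free energy rather than a count surface.  Empty bins
have undefined (NaN) free energy and are excluded from minima and
averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PolyamineModel, SimulationCell
from .mc import Trajectory

__all__ = [
    "LandscapeGrid",
    "default_r_edges",
    "default_mu_edges",
    "reduce_trajectory",
    "accumulate_rho5",
    "free_energy",
    "delta_F",
    "locate_minimum",
]


def default_r_edges(cell: SimulationCell, dr: float = 0.05, r_min: float = 0.55):
    """Radial bin edges Δr = 0.05 nm over [0.55, R_cyl]."""
    n = int(np.floor((cell.R_cyl - r_min) / dr + 1e-9))
    return r_min + dr * np.arange(n + 1)


def default_mu_edges(dmu: float = 0.1):
    """Orientation-cosine bin edges Δμ = 0.1 over [−1, 1]."""
    n = int(round(2.0 / dmu))
    return np.linspace(-1.0, 1.0, n + 1)


@dataclass
class LandscapeGrid:
    """Binned density ρ₅ and free energy F over (r, cosθ)."""

    r_edges: np.ndarray
    mu_edges: np.ndarray
    rho5: np.ndarray  # (n_r, n_mu), per unit phase-space measure
    F_over_kBT: np.ndarray  # −ln ρ₅; NaN on empty bins
    sample_count: np.ndarray  # raw counts
    H: float  # cell height used in the bin measure

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def mu_centers(self) -> np.ndarray:
        return 0.5 * (self.mu_edges[:-1] + self.mu_edges[1:])

    @property
    def bin_measure(self) -> np.ndarray:
        """Jacobian-corrected phase-space element 2π·r̄·Δr·Δμ·H per bin."""
        annulus = np.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)
        return annulus[:, None] * np.diff(self.mu_edges)[None, :] * self.H

    def same_grid(self, other: "LandscapeGrid") -> bool:
        return (
            self.r_edges.shape == other.r_edges.shape
            and self.mu_edges.shape == other.mu_edges.shape
            and np.allclose(self.r_edges, other.r_edges)
            and np.allclose(self.mu_edges, other.mu_edges)
            and np.isclose(self.H, other.H)
        )

    def to_dataframe(self):
        """Long-format table (r_center, mu_center, rho5, F, count)."""
        import pandas as pd

        rr, mm = np.meshgrid(self.r_centers, self.mu_centers, indexing="ij")
        return pd.DataFrame(
            {
                "r_center": rr.ravel(),
                "mu_center": mm.ravel(),
                "rho5": self.rho5.ravel(),
                "F_over_kBT": self.F_over_kBT.ravel(),
                "count": self.sample_count.ravel().astype(int),
            }
        )


def reduce_trajectory(traj: Trajectory, polyamine: PolyamineModel):
    """Collective variables (r, μ) per sample.

    r is the axial-radial distance of the central charged bead (#5 for
    SPD/NSPD); μ the z-component of the unit vector from the first to
    the central charged bead, i.e. cosθ against the DNA axis (for a
    collinear rod this is the rod axis direction).
    """
    idx = polyamine.charged_indices
    if len(idx) < 2:
        raise ValueError("polyamine needs at least two charged beads for (r, mu)")
    mid = idx[len(idx) // 2] - 1
    offset = polyamine.bead_offsets[mid]
    pos = traj.ref[:, :2] + offset * traj.axis[:, :2]
    r = np.hypot(pos[:, 0], pos[:, 1])
    mu = traj.axis[:, 2].copy()  # #1 -> #5 direction is +axis for a rod
    return r, mu


def accumulate_rho5(
    traj: Trajectory,
    polyamine: PolyamineModel,
    r_edges: np.ndarray,
    mu_edges: np.ndarray,
    cell: SimulationCell,
) -> LandscapeGrid:
    """Histogram (r₅, cosθ) into a Jacobian-normalized density grid.

    The density integrates to one over the grid: Σ ρ₅ · (bin measure)
    = 1, with bin measure 2π·r̄·Δr·Δμ·H.  Samples falling outside the
    grid are excluded from the normalization.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    r_edges = np.asarray(r_edges, dtype=float)
    mu_edges = np.asarray(mu_edges, dtype=float)
    if np.any(np.diff(r_edges) <= 0) or np.any(np.diff(mu_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if mu_edges[0] < -1 - 1e-12 or mu_edges[-1] > 1 + 1e-12:
        raise ValueError("mu range must lie within [-1, 1]")
    r, mu = reduce_trajectory(traj, polyamine)
    counts, _, _ = np.histogram2d(r, mu, bins=[r_edges, mu_edges])
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples fall inside the landscape grid")
    grid = LandscapeGrid(
        r_edges=r_edges,
        mu_edges=mu_edges,
        rho5=np.zeros_like(counts),
        F_over_kBT=np.full_like(counts, np.nan),
        sample_count=counts,
        H=cell.H,
    )
    grid.rho5 = counts / total / grid.bin_measure
    return free_energy(grid)


def free_energy(grid: LandscapeGrid) -> LandscapeGrid:
    """Fill F = −ln ρ₅ per bin; empty bins stay NaN (never zero)."""
    with np.errstate(divide="ignore"):
        F = np.where(grid.sample_count > 0, -np.log(grid.rho5), np.nan)
    grid.F_over_kBT = F
    return grid


def delta_F(F_a: LandscapeGrid, F_b: LandscapeGrid) -> LandscapeGrid:
    """Bin-wise free-energy difference F_a − F_b (e.g. SPD − NSPD).

    NaN wherever either input is undefined; positive values mark
    regions the second species occupies preferentially.
    """
    if not F_a.same_grid(F_b):
        raise ValueError("landscapes are on different grids")
    dF = F_a.F_over_kBT - F_b.F_over_kBT
    return LandscapeGrid(
        r_edges=F_a.r_edges.copy(),
        mu_edges=F_a.mu_edges.copy(),
        rho5=np.full_like(dF, np.nan),
        F_over_kBT=dF,
        sample_count=np.minimum(F_a.sample_count, F_b.sample_count),
        H=F_a.H,
    )


def locate_minimum(grid: LandscapeGrid, r_max: float = np.inf):
    """Bin-center (r*, θ*_deg) of the global F minimum with r < r_max.

    θ* = arccos |μ*| in degrees (tilt from the DNA axis).  Ties are
    broken toward smaller r, then smaller |μ|.
    """
    F = grid.F_over_kBT
    rc = grid.r_centers
    mc = grid.mu_centers
    sel = rc < r_max
    if not np.any(sel):
        raise ValueError(f"no bins with r < {r_max}")
    sub = F[sel]
    if np.all(np.isnan(sub)):
        raise ValueError("no defined bins inside r_max")
    fmin = np.nanmin(sub)
    ii, jj = np.where(np.isclose(sub, fmin, rtol=0, atol=1e-12))
    order = np.lexsort((np.abs(mc[jj]), rc[sel][ii]))
    i, j = ii[order[0]], jj[order[0]]
    r_star = rc[sel][i]
    theta_star = float(np.degrees(np.arccos(min(abs(mc[j]), 1.0))))
    return float(r_star), theta_star
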