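"""Coarse-grained geometry of trivalent polyamines and a DNA segment.

Spermidine (SPD, [N-3-N-4-N]) and norspermidine (NSPD, [N-3-N-3-N]) are
represented as rigid rods of tangent beads of diameter ``d`` = 0.39 nm.
Each protonated amine (ammonium) bead carries +1 unit charge: SPD is a
10-bead rod with ammoniums at positions #1, #5, #10; NSPD a 9-bead rod
with ammoniums at #1, #5, #9 (1-based, as drawn on the chemical
structure).

The DNA segment is a "soft cylinder": ``n_pairs`` pairs of −1 charged
phosphate spheres (diameter σ = 0.476 nm) on a cylinder of radius
``R_DNA`` = 1.0 nm, the two members of each pair 180° apart, successive
pairs 0.34 nm apart along the axis.  The simulation cell is a coaxial
cylinder of height H (= axial span of the DNA, periodic) and radius
``R_cyl``.

All lengths are in nm; the DNA axis is the z-axis and the cell is
{x² + y² ≤ R_cyl², 0 ≤ z < H} with z periodic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolyamineModel",
    "DNAModel",
    "SimulationCell",
    "build_polyamine",
    "build_dna",
    "build_cell",
    "hbond_contact_distance",
    "write_xyz",
    "SPECIES_TABLE",
]

#: bead count and 1-based charged-bead indices per species
SPECIES_TABLE = {
    "SPD": (10, (1, 5, 10)),
    "NSPD": (9, (1, 5, 9)),
}

DEFAULT_BEAD_DIAMETER = 0.39  # nm, methylene/ammonium bead
DEFAULT_PAIR_SPACING = 0.34  # nm, axial rise per phosphate pair
DEFAULT_R_DNA = 1.0  # nm, soft-cylinder radius
DEFAULT_SIGMA = 0.476  # nm, phosphate sphere diameter


@dataclass(frozen=True)
class PolyamineModel:
    """Rigid linear bead-chain model of a trivalent polyamine."""

    species_name: str
    n_beads: int
    bead_diameter: float
    charged_indices: tuple[int, ...]  # 1-based
    bead_positions_body_frame: np.ndarray  # (n_beads, 3), rod along +z

    @property
    def rod_length(self) -> float:
        """End-to-end bead-center distance, (n_beads − 1)·d."""
        return (self.n_beads - 1) * self.bead_diameter

    @property
    def charges(self) -> np.ndarray:
        """Per-bead charge in unit charges (+1 on each ammonium)."""
        q = np.zeros(self.n_beads)
        q[[i - 1 for i in self.charged_indices]] = 1.0
        return q

    @property
    def bead_offsets(self) -> np.ndarray:
        """Scalar position of each bead along the rod axis from bead #1."""
        return np.arange(self.n_beads) * self.bead_diameter

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass(frozen=True)
class DNAModel:
    """Phosphate-sphere model of a double-stranded DNA segment."""

    n_pairs: int
    pair_spacing: float
    phosphate_diameter: float
    R_DNA: float
    twist_per_pair: float  # degrees
    phosphate_positions: np.ndarray  # (2·n_pairs, 3)

    @property
    def n_phosphates(self) -> int:
        return 2 * self.n_pairs

    @property
    def total_charge(self) -> float:
        return -float(self.n_phosphates)

    @property
    def axial_span(self) -> float:
        return self.n_pairs * self.pair_spacing


@dataclass(frozen=True)
class SimulationCell:
    """Cylindrical cell, periodic along the DNA (z) axis."""

    H: float = 3.4
    R_cyl: float = 2.591
    periodic_axis: bool = True

    @property
    def volume(self) -> float:
        return math.pi * self.R_cyl**2 * self.H

    def wrap_z(self, z):
        """Wrap axial coordinate(s) into [0, H)."""
        return np.mod(z, self.H)

    def min_image_dz(self, dz):
        """Minimum-image axial separation."""
        return dz - self.H * np.round(np.asarray(dz) / self.H)


def build_polyamine(
    species: str,
    d: float = DEFAULT_BEAD_DIAMETER,
    *,
    n_beads: int | None = None,
    charged_indices: tuple[int, ...] | None = None,
) -> PolyamineModel:
    """Construct a rigid-rod polyamine model.

    Parameters
    ----------
    species
        ``"SPD"`` or ``"NSPD"``; any other label requires explicit
        ``n_beads`` and ``charged_indices`` (used for reduced test
        systems).
    d
        Bead diameter = center-to-center spacing (tangent spheres), nm.
    """
    if d <= 0:
        raise ValueError(f"bead diameter must be positive, got {d}")
    key = species.upper()
    if key in SPECIES_TABLE:
        nb, ci = SPECIES_TABLE[key]
        if n_beads is not None and n_beads != nb:
            raise ValueError(f"{key} has {nb} beads, not {n_beads}")
        charged = ci if charged_indices is None else tuple(charged_indices)
    else:
        if n_beads is None or charged_indices is None:
            raise ValueError(
                f"unknown polyamine species {species!r}: expected one of "
                f"{sorted(SPECIES_TABLE)} (or give n_beads and charged_indices)"
            )
        nb, charged = n_beads, tuple(charged_indices)
    if not all(1 <= i <= nb for i in charged):
        raise ValueError(f"charged indices {charged} outside 1..{nb}")
    pos = np.zeros((nb, 3))
    pos[:, 2] = np.arange(nb) * d
    return PolyamineModel(
        species_name=key,
        n_beads=nb,
        bead_diameter=d,
        charged_indices=tuple(charged),
        bead_positions_body_frame=pos,
    )


def build_dna(
    n_pairs: int = 10,
    spacing: float = DEFAULT_PAIR_SPACING,
    R_DNA: float = DEFAULT_R_DNA,
    sigma: float = DEFAULT_SIGMA,
    twist_per_pair: float = 0.0,
) -> DNAModel:
    """Place ``2·n_pairs`` phosphate spheres on the soft DNA cylinder.

    Pair ``k`` (k = 0 .. n_pairs−1) sits at axial coordinate
    ``k·spacing``; its two phosphates are at azimuth ``k·twist_per_pair``
    and that plus 180°, both at radius ``R_DNA``.  Default twist is 0°
    (straight phosphate ladder): only the 180° intra-pair separation is
    part of the model; helical twist is configurable for sensitivity
    checks.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if spacing <= 0 or R_DNA <= 0 or sigma <= 0:
        raise ValueError("spacing, R_DNA and sigma must be positive")
    k = np.arange(n_pairs)
    phi = np.deg2rad(k * twist_per_pair)
    z = k * spacing
    first = np.column_stack([R_DNA * np.cos(phi), R_DNA * np.sin(phi), z])
    second = np.column_stack([-R_DNA * np.cos(phi), -R_DNA * np.sin(phi), z])
    pos = np.empty((2 * n_pairs, 3))
    pos[0::2] = first
    pos[1::2] = second
    return DNAModel(
        n_pairs=n_pairs,
        pair_spacing=spacing,
        phosphate_diameter=sigma,
        R_DNA=R_DNA,
        twist_per_pair=twist_per_pair,
        phosphate_positions=pos,
    )


def build_cell(R_cyl: float = 2.591, dna: DNAModel | None = None) -> SimulationCell:
    """Cell matching the DNA axial span (H = n_pairs · spacing)."""
    H = dna.axial_span if dna is not None else 3.4
    if R_cyl <= 0:
        raise ValueError("R_cyl must be positive")
    return SimulationCell(H=H, R_cyl=R_cyl)


def hbond_contact_distance(
    angle_deg: float,
    r_N: float = 0.137,
    d_HB: float = 0.174,
    r_P: float = 0.258,
) -> float:
    """Ammonium-N to phosphate-P center distance at a given H-bond angle.

    The N-H···O-P contact is modeled as a triangle with its vertex at the
    hydrogen-bond-accepting oxygen: one side is the nitrogen-to-oxygen
    distance ``r_N + d_HB`` (ammonium ionic radius plus hydrogen-bond
    length), the other the phosphate ionic radius ``r_P``, with the
    hydrogen-bond angle between them.  The law of cosines then gives the
    N–P distance: 0.404 nm at 90°, 0.453 nm at 105° (the adopted binding
    cutoff) and 0.569 nm in the fully extended 180° geometry.

    Parameters use ionic radii of ammonium (0.137 nm) and of sulfate as a
    phosphate stand-in (0.258 nm), and an N-H···O hydrogen-bond length of
    0.174 nm.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError(f"hydrogen-bond angle must be in [0, 180], got {angle_deg}")
    if min(r_N, d_HB, r_P) <= 0:
        raise ValueError("radii and hydrogen-bond length must be positive")
    a = r_N + d_HB
    b = r_P
    c2 = a * a + b * b - 2.0 * a * b * math.cos(math.radians(angle_deg))
    return math.sqrt(max(c2, 0.0))


def write_xyz(path, polyamine=None, dna=None, bead_positions=None, comment=""):
    """Write an XYZ snapshot of the model for visual inspection.

    One record per bead/phosphate; element tags are ``N`` (ammonium),
    ``C`` (neutral bead) and ``P`` (phosphate).  ``bead_positions``
    overrides the body-frame rod coordinates of the polyamine (e.g. a
    sampled configuration).
    """
    records = []
    if polyamine is not None:
        pos = (
            polyamine.bead_positions_body_frame
            if bead_positions is None
            else np.asarray(bead_positions)
        )
        charged = set(polyamine.charged_indices)
        for i, p in enumerate(pos, start=1):
            records.append(("N" if i in charged else "C", p))
    if dna is not None:
        for p in dna.phosphate_positions:
            records.append(("P", p))
    with open(path, "w") as fh:
        fh.write(f"{len(records)}\n{comment}\n")
        for tag, p in records:
            fh.write(f"{tag} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
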