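import math

import numpy as np
import pytest

import polyamine_dna as pdna
from polyamine_dna.energy import Configuration, EnergyParams, pair_energy, total_energy


def brute_force_energy(config, polyamine, dna, params, cell):
    """Independent plain-loop oracle for the total reduced energy."""
    beads = [
        config.ref_position + off * config.orientation
        for off in polyamine.bead_offsets
    ]
    charges = polyamine.charges
    contact = 0.5 * (polyamine.bead_diameter + dna.phosphate_diameter)
    e = 0.0
    for i, b in enumerate(beads):
        rho = math.hypot(b[0], b[1])
        if rho > cell.R_cyl:
            return math.inf
        if rho < dna.R_DNA:
            e += 0.5 * params.soft_k * (dna.R_DNA - rho) ** 2
        for p in dna.phosphate_positions:
            dz = b[2] - p[2]
            dz -= cell.H * round(dz / cell.H)
            r = math.sqrt((b[0] - p[0]) ** 2 + (b[1] - p[1]) ** 2 + dz**2)
            if params.hard_core and r < contact:
                return math.inf
            if charges[i]:
                screen = (
                    math.exp(-r / params.debye_length)
                    if math.isfinite(params.debye_length)
                    else 1.0
                )
                e += params.Gamma * charges[i] * (-1.0) * screen / r
    return e


class TestPairEnergy:
    def test_contact_coupling_at_unit_distance(self):
        p = EnergyParams(Gamma=1.36, debye_length=math.inf)
        assert pair_energy(1.0, +1, -1, p) == pytest.approx(-1.36)

    def test_uncharged_bead(self):
        p = EnergyParams()
        assert pair_energy(0.7, 0, -1, p) == 0.0

    def test_screening_factor_at_one_debye_length(self):
        lam = 2.2
        screened = EnergyParams(Gamma=1.36, debye_length=lam)
        bare = EnergyParams(Gamma=1.36, debye_length=math.inf)
        assert pair_energy(lam, +1, -1, screened) == pytest.approx(
            pair_energy(lam, +1, -1, bare) * math.exp(-1)
        )

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(0.0, 1, -1, EnergyParams())


class TestTotalEnergy:
    def test_zero_charges_no_penetration(self, dna, cell):
        pa = pdna.build_polyamine("rod", n_beads=3, charged_indices=(1,))
        # neutralize by zeroing Gamma rather than the model's charges
        cfg = Configuration(np.array([1.8, 0.0, 1.0]), np.array([0.0, 0.0, 1.0]))
        p = EnergyParams(Gamma=0.0)
        assert total_energy(cfg, pa, dna, p, cell) == 0.0

    @pytest.mark.parametrize("lam", [math.inf, 3.04, 0.7])
    def test_matches_brute_force(self, spd, dna, cell, lam):
        rng = np.random.default_rng(42)
        p = EnergyParams(debye_length=lam)
        checked = 0
        for _ in range(40):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            ref = np.array([rng.uniform(-2, 2), rng.uniform(-2, 2), rng.uniform(0, 3.4)])
            cfg = Configuration(ref, u)
            expected = brute_force_energy(cfg, spd, dna, p, cell)
            got = total_energy(cfg, spd, dna, p, cell)
            if math.isinf(expected):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)
                checked += 1
        assert checked >= 5  # enough finite configurations exercised

    def test_mirror_symmetry_straight_ladder(self, spd, dna, cell):
        # twist = 0: reflection through the xz-plane preserves the model
        p = EnergyParams()
        rng = np.random.default_rng(3)
        for _ in range(10):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            ref = np.array([1.7, 0.4, 1.2])
            mirrored_u = u * np.array([1.0, -1.0, 1.0])
            mirrored_ref = ref * np.array([1.0, -1.0, 1.0])
            e1 = total_energy(Configuration(ref, u), spd, dna, p, cell)
            e2 = total_energy(Configuration(mirrored_ref, mirrored_u), spd, dna, p, cell)
            assert e1 == pytest.approx(e2, abs=1e-12)

    def test_hard_core_overlap_infinite(self, spd, dna, cell):
        # bead #1 right on top of a phosphate
        cfg = Configuration(np.array([1.0, 0.0, 0.1]), np.array([0.0, 0.0, 1.0]))
        assert math.isinf(total_energy(cfg, spd, dna, EnergyParams(), cell))

    def test_outside_wall_infinite(self, spd, dna, cell):
        cfg = Configuration(np.array([2.7, 0.0, 1.0]), np.array([0.0, 0.0, 1.0]))
        assert math.isinf(total_energy(cfg, spd, dna, EnergyParams(), cell))

    def test_soft_envelope_penalty_value(self, dna, cell):
        # uncharged single bead at depth 0.3 nm inside the envelope
        pa = pdna.build_polyamine("probe", n_beads=2, charged_indices=(1,))
        p = EnergyParams(Gamma=0.0, soft_k=10.0, hard_core=False)
        cfg = Configuration(np.array([0.7, 0.0, 0.17]), np.array([0.0, 0.0, 1.0]))
        # both beads at rho = 0.7: 2 × ½·10·0.3²
        assert total_energy(cfg, pa, dna, p, cell) == pytest.approx(0.9)


def test_params_validation():
    with pytest.raises(ValueError):
        EnergyParams(Gamma=-1)
    with pytest.raises(ValueError):
        EnergyParams(debye_length=0)


def test_configuration_requires_unit_axis():
    with pytest.raises(ValueError):
        Configuration(np.zeros(3), np.array([0.0, 0.0, 2.0]))
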