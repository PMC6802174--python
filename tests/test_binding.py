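import math

import numpy as np
import pytest
from scipy.integrate import quad

import polyamine_dna as pdna
from polyamine_dna.binding import NM3_TO_MM, BindingParams
from polyamine_dna.energy import Configuration

from test_landscape import make_trajectory


def brute_force_bound(traj, polyamine, dna, cell, cutoff):
    """Plain-loop oracle for the simultaneous three-ammonium criterion."""
    out = []
    for i in range(len(traj)):
        beads = traj.ref[i] + np.outer(polyamine.bead_offsets, traj.axis[i])
        ok = True
        for idx in polyamine.charged_indices:
            b = beads[idx - 1]
            best = math.inf
            for p in dna.phosphate_positions:
                dz = b[2] - p[2]
                dz -= cell.H * round(dz / cell.H)
                d = math.sqrt((b[0] - p[0]) ** 2 + (b[1] - p[1]) ** 2 + dz**2)
                best = min(best, d)
            if best >= cutoff:
                ok = False
                break
        out.append(ok)
    return np.array(out)


class TestIsBound:
    def test_simultaneity_requirement(self, spd, dna, cell):
        # rod parallel to the axis, 0.42 nm outside a phosphate rail:
        # all three ammonium-phosphate distances fall below the cutoff
        cfg = Configuration(np.array([1.42, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
        assert pdna.is_bound(cfg, spd, dna, cell, cutoff=0.453)
        # a tighter cutoff than the largest of the three distances breaks it
        beads = cfg.bead_positions(spd)
        amm = beads[[0, 4, 9]]
        dmax = max(
            min(
                np.sqrt(
                    (a[0] - p[0]) ** 2 + (a[1] - p[1]) ** 2
                    + cell.min_image_dz(a[2] - p[2]) ** 2
                )
                for p in dna.phosphate_positions
            )
            for a in amm
        )
        assert not pdna.is_bound(cfg, spd, dna, cell, cutoff=dmax * 0.999)

    def test_wall_pose_unbound(self, spd, dna, cell):
        cfg = Configuration(np.array([2.4, 0.0, 1.0]), np.array([0.0, 0.0, 1.0]))
        assert not pdna.is_bound(cfg, spd, dna, cell)

    def test_mask_matches_plain_loop(self, production_runs, nspd, dna, cell):
        traj = production_runs[("NSPD", 1)]
        import dataclasses

        sub = dataclasses.replace(
            traj, ref=traj.ref[:200], axis=traj.axis[:200], energy=traj.energy[:200]
        )
        fast = pdna.bound_mask(sub, nspd, dna, cell, 0.453)
        slow = brute_force_bound(sub, nspd, dna, cell, 0.453)
        assert np.array_equal(fast, slow)


class TestPhaseVolumes:
    def test_closed_form_quadrature(self, dna, cell):
        """V_b and V_f against independent numeric quadrature."""
        params = BindingParams()
        V_b, V_f = pdna.phase_volumes(cell, dna, params)
        r_in = dna.R_DNA - dna.phosphate_diameter / 2
        radial_in = 2 * math.pi * cell.H * quad(lambda r: r, r_in, params.R_cut)[0]
        radial_out = 2 * math.pi * cell.H * quad(lambda r: r, params.R_cut, cell.R_cyl)[0]
        mu_b = 2 * quad(lambda m: 2 * math.pi, 0.5, 1.0)[0]
        mu_f = 2 * quad(lambda m: 2 * math.pi, 0.0, 0.5)[0]
        assert V_b == pytest.approx(radial_in * mu_b, rel=1e-12)
        # literal outer term: 4πH ∫ r dr = 2 × (2πH ∫ r dr)
        assert V_f == pytest.approx(radial_in * mu_f + 2 * radial_out, rel=1e-12)
        # frozen reference numbers for the study geometry
        assert radial_in == pytest.approx(11.8494, abs=1e-3)
        assert V_b == pytest.approx(74.449, abs=5e-3)
        assert 2 * radial_out == pytest.approx(107.31, abs=2e-2)

    def test_consistent_variant(self, dna, cell):
        lit = pdna.phase_volumes(cell, dna, BindingParams(literal_outer=True))
        con = pdna.phase_volumes(cell, dna, BindingParams(literal_outer=False))
        assert lit[0] == con[0]  # bound volume unaffected
        assert con[1] > lit[1]  # full 4π orientation measure is larger

    def test_radial_ordering_enforced(self, dna, cell):
        with pytest.raises(ValueError):
            pdna.phase_volumes(cell, dna, BindingParams(R_cut=0.5))
        with pytest.raises(ValueError):
            pdna.phase_volumes(cell, dna, BindingParams(R_cut=3.0))


class TestBindingK:
    def test_no_bound_samples_zero(self, spd, dna, cell):
        traj = make_trajectory(
            [((2.4, 0.0, z), (0.0, 0.0, 1.0)) for z in np.linspace(0, 3, 20)]
        )
        res = pdna.binding_K(traj, spd, dna, cell)
        assert res.K_per_mM == 0.0
        assert res.N_binding + res.N_nonbinding == 1.0

    def test_half_bound_equal_volumes(self, spd, dna, cell):
        # one bound pose, one far pose; R_cut → R_cyl kills the outer
        # term and the equal μ-slabs make V_b = V_f, so K = 1/[Phosphate]
        params = BindingParams(R_cut=cell.R_cyl - 1e-9)
        traj = make_trajectory(
            [((1.42, 0.0, 0.0), (0, 0, 1.0)), ((2.4, 0.0, 1.0), (0, 0, 1.0))]
        )
        res = pdna.binding_K(traj, spd, dna, cell, params)
        assert res.N_binding == 0.5
        conc = pdna.phosphate_concentration_mM(dna, cell)
        assert res.K_per_mM == pytest.approx(1.0 / conc, rel=1e-6)

    def test_all_bound_unmeasurable(self, spd, dna, cell):
        traj = make_trajectory([((1.42, 0.0, 0.0), (0, 0, 1.0))] * 4)
        res = pdna.binding_K(traj, spd, dna, cell)
        assert res.K_per_mM is None

    def test_half_trajectory_consistency(self, production_runs, nspd, dna, cell):
        """K from disjoint halves agrees within combined block errors."""
        import dataclasses

        traj = production_runs[("NSPD", 3)]
        m = len(traj) // 2
        halves = [
            dataclasses.replace(
                traj, ref=traj.ref[s], axis=traj.axis[s], energy=traj.energy[s]
            )
            for s in (slice(0, m), slice(m, None))
        ]
        res = [pdna.binding_K(h, nspd, dna, cell) for h in halves]
        err = math.hypot(res[0].K_stderr, res[1].K_stderr)
        assert abs(res[0].K_per_mM - res[1].K_per_mM) <= 3 * err

    def test_r_cut_conditioning_variant(self, production_runs, spd, dna, cell):
        traj = production_runs[("SPD", 1)]
        plain = pdna.binding_K(traj, spd, dna, cell)
        conditioned = pdna.binding_K(
            traj, spd, dna, cell, BindingParams(require_within_R_cut=True)
        )
        assert conditioned.N_binding <= plain.N_binding


def test_phosphate_concentration(dna, cell):
    conc = pdna.phosphate_concentration_mM(dna, cell)
    expected = 20 / (math.pi * 2.591**2 * 3.4) * NM3_TO_MM
    assert conc == pytest.approx(expected, rel=1e-12)


def test_gamma_sweep_zero_coupling(dna, cell):
    df = pdna.gamma_sweep(
        ["SPD", "NSPD"], [0.0], [2.591], seeds=[4],
        n_equil=20_000, n_prod=200_000,
    )
    assert set(df["species"]) == {"SPD", "NSPD"}
    assert (df["N_binding"] <= 1e-3).all()  # no attraction: contact-scale only
    assert (df["K_per_mM"] >= 0).all()
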