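import dataclasses

import numpy as np
import pytest

import polyamine_dna as pdna
from polyamine_dna.landscape import LandscapeGrid


def make_trajectory(samples, species="SPD"):
    """Hand-built trajectory from (ref, axis) tuples."""
    ref = np.array([s[0] for s in samples], dtype=float)
    axis = np.array([s[1] for s in samples], dtype=float)
    return pdna.Trajectory(
        species=species, seed=0, stride=1, n_equil=0, n_prod=len(samples),
        ref=ref, axis=axis, energy=np.zeros(len(samples)),
        acceptance_equil=0.0, acceptance_prod=0.0, max_trans=0.1, max_rot=0.1,
    )


def make_grid(rho, r_edges, mu_edges, H=3.4, counts=None):
    rho = np.asarray(rho, dtype=float)
    grid = LandscapeGrid(
        r_edges=np.asarray(r_edges, dtype=float),
        mu_edges=np.asarray(mu_edges, dtype=float),
        rho5=rho,
        F_over_kBT=np.full_like(rho, np.nan),
        sample_count=np.ones_like(rho) if counts is None else np.asarray(counts),
        H=H,
    )
    return pdna.free_energy(grid)


class TestAccumulate:
    def test_hand_histogram(self, spd, cell):
        # two samples with (r5 ≈ 0.5, μ = 1), one with (r5 ≈ 1.5, μ = −1)
        up = (0.0, 0.0, 1.0)
        down = (0.0, 0.0, -1.0)
        traj = make_trajectory(
            [((0.5, 0, 1.0), up), ((0, 0.5, 2.0), up), ((1.5, 0, 1.0), down)]
        )
        grid = pdna.accumulate_rho5(traj, spd, [0, 1, 2], [-1, 0, 1], cell)
        assert grid.sample_count.tolist() == [[0, 2], [1, 0]]

    def test_normalization_invariant(self, production_runs, spd, cell):
        traj = production_runs[("SPD", 1)]
        for dr, dmu in ((0.05, 0.1), (0.1, 0.2)):
            grid = pdna.accumulate_rho5(
                traj, spd,
                pdna.default_r_edges(cell, dr), pdna.default_mu_edges(dmu), cell,
            )
            assert np.sum(grid.rho5 * grid.bin_measure) == pytest.approx(1.0, abs=1e-9)

    def test_empty_trajectory_rejected(self, spd, cell):
        traj = make_trajectory([((0.5, 0, 1.0), (0, 0, 1.0))])
        empty = dataclasses.replace(
            traj, ref=traj.ref[:0], axis=traj.axis[:0], energy=traj.energy[:0]
        )
        with pytest.raises(ValueError, match="empty"):
            pdna.accumulate_rho5(empty, pdna.build_polyamine("SPD"),
                                 [0, 1], [-1, 1], cell)

    def test_bad_edges_rejected(self, spd, cell):
        traj = make_trajectory([((0.5, 0, 1.0), (0, 0, 1.0))])
        with pytest.raises(ValueError):
            pdna.accumulate_rho5(traj, spd, [1, 1], [-1, 1], cell)
        with pytest.raises(ValueError):
            pdna.accumulate_rho5(traj, spd, [0, 1], [-1, 1.5], cell)


class TestFreeEnergy:
    def test_log_transform(self):
        grid = make_grid([[1.0, np.e**-2]], [0, 1], [-1, 0, 1])
        assert grid.F_over_kBT[0, 0] == pytest.approx(0.0)
        assert grid.F_over_kBT[0, 1] == pytest.approx(2.0)

    def test_empty_bin_undefined(self):
        grid = make_grid([[0.5, 0.0]], [0, 1], [-1, 0, 1], counts=[[5, 0]])
        assert np.isnan(grid.F_over_kBT[0, 1])

    def test_minimum_at_density_maximum(self, production_runs, nspd, cell):
        traj = production_runs[("NSPD", 2)]
        grid = pdna.accumulate_rho5(
            traj, nspd, pdna.default_r_edges(cell), pdna.default_mu_edges(), cell
        )
        imax = np.unravel_index(np.argmax(grid.rho5), grid.rho5.shape)
        imin = np.unravel_index(np.nanargmin(grid.F_over_kBT), grid.F_over_kBT.shape)
        assert imax == imin


class TestDeltaF:
    def test_identical_landscapes_zero(self):
        g = make_grid([[0.5, 0.25]], [0, 1], [-1, 0, 1])
        d = pdna.delta_F(g, g)
        assert np.allclose(d.F_over_kBT, 0.0)

    def test_antisymmetry(self):
        a = make_grid([[0.5, 0.25]], [0, 1], [-1, 0, 1])
        b = make_grid([[0.25, 0.5]], [0, 1], [-1, 0, 1])
        assert np.allclose(
            pdna.delta_F(a, b).F_over_kBT, -pdna.delta_F(b, a).F_over_kBT
        )

    def test_undefined_propagates(self):
        a = make_grid([[0.5, 0.0]], [0, 1], [-1, 0, 1], counts=[[1, 0]])
        b = make_grid([[0.5, 0.25]], [0, 1], [-1, 0, 1])
        assert np.isnan(pdna.delta_F(a, b).F_over_kBT[0, 1])

    def test_mismatched_grids_rejected(self):
        a = make_grid([[0.5, 0.25]], [0, 1], [-1, 0, 1])
        b = make_grid([[0.5, 0.25]], [0, 2], [-1, 0, 1])
        with pytest.raises(ValueError, match="different grids"):
            pdna.delta_F(a, b)


class TestLocateMinimum:
    def test_single_bin(self):
        g = make_grid([[0.7]], [0.5, 1.0], [0, 1])
        assert pdna.locate_minimum(g) == (pytest.approx(0.75), pytest.approx(60.0))

    def test_planted_gaussian_well(self):
        r_edges = np.linspace(0.5, 2.5, 41)
        mu_edges = np.linspace(-1, 1, 21)
        rc = 0.5 * (r_edges[:-1] + r_edges[1:])
        mc = 0.5 * (mu_edges[:-1] + mu_edges[1:])
        rr, mm = np.meshgrid(rc, mc, indexing="ij")
        r0, mu0 = 1.12, 0.71  # tilt ≈ 44.77°
        rho = np.exp(-((rr - r0) ** 2) / 0.02 - ((mm - mu0) ** 2) / 0.02)
        g = make_grid(rho, r_edges, mu_edges)
        r_star, theta = pdna.locate_minimum(g, r_max=2.0)
        assert abs(r_star - r0) <= 0.05
        assert abs(theta - np.degrees(np.arccos(mu0))) <= np.degrees(0.1)

    def test_tie_break_smaller_r_then_axis(self):
        rho = np.array([[0.5, 0.5], [0.5, 0.5]])
        g = make_grid(rho, [0, 1, 2], [-1, 0, 1])
        r_star, theta = pdna.locate_minimum(g)
        assert r_star == pytest.approx(0.5)

    def test_no_defined_bins_rejected(self):
        g = make_grid([[0.1]], [2.0, 3.0], [0, 1])
        with pytest.raises(ValueError):
            pdna.locate_minimum(g, r_max=1.0)
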