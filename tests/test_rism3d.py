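import numpy as np
import pytest
from scipy.fft import irfftn, rfftn
from scipy.ndimage import map_coordinates

from ecrism import constants
from ecrism.closures import ClosureSpec
from ecrism.fixtures import direct_convolution, make_fixture
from ecrism.forcefield import Site, SoluteModel, ThermoState
from ecrism.free_energy import excess_mu
from ecrism.rism3d import (
    Grid3D,
    _fft_friendly,
    apply_closure,
    build_grid,
    solute_site_potentials,
    solve_3drism,
)


def _solvent_sites(sus):
    return [sus.type_site(lab) for lab in sus.unique_types]


class TestBuildGrid:
    def test_single_atom_box(self, lj_fixture):
        grid = build_grid(lj_fixture.solute, buffer=15.0, spacing=0.3)
        assert all(d >= 100 for d in grid.dims)
        assert np.all(grid.box_lengths >= 30.0)

    def test_buffer_monotone_volume(self, lj_fixture):
        v5 = np.prod(build_grid(lj_fixture.solute, 5.0, 0.3).box_lengths)
        v15 = np.prod(build_grid(lj_fixture.solute, 15.0, 0.3).box_lengths)
        assert v15 > v5

    def test_two_atom_rounding(self):
        solute = SoluteModel(
            ("C", "C"), np.array([[0.0, 0, 0], [4.0, 0, 0]]),
            (Site("C", 0.0, 3.4, 0.5),) * 2,
        )
        grid = build_grid(solute, buffer=10.0, spacing=0.5)
        # x edge >= 24 Å -> >= 48 voxels, rounded up to an FFT-friendly size
        assert grid.dims[0] == _fft_friendly(48)
        assert grid.box_lengths[0] >= 24.0

    def test_faces_respect_buffer(self, dipolar_fixture):
        grid = build_grid(dipolar_fixture.solute, buffer=7.0, spacing=0.5)
        lo = np.asarray(grid.origin) - 0.5 * np.asarray(grid.spacing)
        hi = lo + grid.box_lengths
        pos = dipolar_fixture.solute.positions
        assert np.all(pos.min(axis=0) - lo >= 7.0 - 1e-9)
        assert np.all(hi - pos.max(axis=0) >= 7.0 - 1e-9)

    def test_degenerate_spacing_rejected(self, lj_fixture):
        with pytest.raises(ValueError):
            build_grid(lj_fixture.solute, buffer=1.0, spacing=10.0)

    def test_fft_friendly_values(self):
        assert _fft_friendly(48) == 48
        assert _fft_friendly(101) == 108
        assert _fft_friendly(43) == 48  # 44 = 4*11 is not 7-smooth
        for n in (12, 100, 121, 250):
            m = _fft_friendly(n)
            assert m >= n and m % 2 == 0
            k = m
            for p in (2, 3, 5, 7):
                while k % p == 0:
                    k //= p
            assert k == 1


class TestPotentials:
    def test_zero_charges_pure_lj(self, lj_fixture, sus_pse3):
        grid = build_grid(lj_fixture.solute, 5.0, 1.0)
        pots = solute_site_potentials(lj_fixture.solute, _solvent_sites(sus_pse3), grid)
        assert np.all(pots.phi_long == 0.0)
        assert np.all(pots.phi_long_periodic == 0.0)

    def test_superposition_bitwise(self, sus_pse3):
        sites = _solvent_sites(sus_pse3)
        s_ab = SoluteModel(
            ("C", "N"), np.array([[0.0, 0, 0], [2.0, 0.5, 0]]),
            (Site("C", 0.2, 3.4, 0.5), Site("N", -0.2, 3.2, 0.7)),
        )
        grid = build_grid(s_ab, 5.0, 1.0)
        u_ab = solute_site_potentials(s_ab, sites, grid).u_short
        u_sum = np.zeros_like(u_ab)
        for i in range(2):
            single = SoluteModel(
                (s_ab.elements[i],), s_ab.positions[i:i + 1], (s_ab.sites[i],)
            )
            u_sum += solute_site_potentials(single, sites, grid).u_short
        assert np.array_equal(u_ab, u_sum)

    def test_coulomb_split_reconstruction(self):
        # unit solute charge, unit probe site: short + long = k_e / r exactly
        solute = SoluteModel(("H",), np.zeros((1, 3)), (Site("H", 1.0, 0.0, 0.0),))
        probe = Site("P", 1.0, 0.0, 0.0)
        grid = build_grid(solute, 8.0, 1.0)
        pots = solute_site_potentials(solute, [probe], grid)
        x, y, z = grid.axes()
        ix, iy, iz = np.argmin(np.abs(x - 3.0)), np.argmin(np.abs(y)), np.argmin(np.abs(z - 4.0))
        r = np.sqrt(x[ix] ** 2 + y[iy] ** 2 + z[iz] ** 2)
        total = pots.u_short[0, ix, iy, iz] + 1.0 * pots.phi_long[ix, iy, iz]
        assert total == pytest.approx(constants.COULOMB / r, rel=1e-6)

    def test_invalid_solvent_site_signalled(self, lj_fixture):
        bad = Site("X", 0.0, 0.0, 0.5)
        grid = build_grid(lj_fixture.solute, 5.0, 1.0)
        with pytest.raises(ValueError, match="zero sigma"):
            solute_site_potentials(lj_fixture.solute, [bad], grid)

    def test_periodic_field_matches_open_near_center(self, dipolar_fixture, sus_pse3):
        # Away from the faces the Ewald-style field equals the open-space one.
        grid = build_grid(dipolar_fixture.solute, 12.0, 0.5)
        pots = solute_site_potentials(
            dipolar_fixture.solute, _solvent_sites(sus_pse3), grid
        )
        n = grid.dims[0] // 2
        sl = (slice(n - 6, n + 6),) * 3
        # The periodic field differs from the open one by the image background,
        # which is nearly uniform at the box center: compare after removing it.
        diff = pots.phi_long_periodic[sl] - pots.phi_long[sl]
        assert np.ptp(diff) < 0.2 * np.ptp(pots.phi_long[sl])


def test_apply_closure_wrapper(thermo):
    u = np.array([[0.0, 1.0]])
    gamma = np.zeros_like(u)
    g = apply_closure(u, gamma, ClosureSpec("KH"), thermo)
    assert g[0, 0] == 1.0
    assert g[0, 1] == pytest.approx(np.exp(-thermo.beta))
    with pytest.raises(ValueError):
        apply_closure(u, np.zeros((3, 3)), ClosureSpec("KH"), thermo)


class TestSolve3D:
    def test_no_potential_trivial_fixed_point(self, sus_pse3, thermo):
        solute = SoluteModel(("He",), np.zeros((1, 3)), (Site("He", 0.0, 0.0, 0.0),))
        grid = build_grid(solute, 5.0, 1.0)
        pots = solute_site_potentials(solute, _solvent_sites(sus_pse3), grid)
        corr = solve_3drism(pots, sus_pse3, ClosureSpec("PSE", 3), thermo=thermo)
        assert len(corr.residual_history) == 1  # converged on the first check
        assert np.allclose(corr.h, 0.0, atol=1e-12)
        assert np.allclose(corr.c, 0.0, atol=1e-12)

    def test_spectral_convolution_against_direct_oracle(self, rng):
        c = rng.standard_normal((8, 8, 8))
        kernel = rng.standard_normal((8, 8, 8))
        spectral = irfftn(rfftn(c) * rfftn(kernel), s=c.shape)
        assert spectral == pytest.approx(direct_convolution(c, kernel), abs=1e-10)

    def test_oz_relation_satisfied_at_convergence(self, lj_solution, sus_pse3):
        corr, _ = lj_solution
        grid = corr.grid
        kmag = grid.k_magnitude()
        from ecrism.rism3d import _collapsed_chi

        x_chi = _collapsed_chi(sus_pse3, kmag)
        beta = corr.thermo.beta
        c_hat = np.array([rfftn(corr.c[t]) for t in range(corr.n_types)])
        for t in range(corr.n_types):
            acc = sum(c_hat[tp] * x_chi[tp, t] for tp in range(corr.n_types))
            h_oz = irfftn(acc, s=grid.dims)
            assert np.sqrt(np.mean((h_oz - corr.h[t]) ** 2)) < 5e-6

    def test_lj_sphere_spherical_symmetry(self, lj_solution):
        corr, _ = lj_solution
        grid = corr.grid
        # all 48 octahedral images of one probe point share the radius, and
        # the cubic grid is symmetric about the solute, so trilinear samples
        # must agree to solver precision
        from itertools import permutations

        base = np.array([1.3, 2.1, 3.2])
        pts = []
        for perm in permutations(range(3)):
            for sx in (1, -1):
                for sy in (1, -1):
                    for sz in (1, -1):
                        pts.append(base[list(perm)] * np.array([sx, sy, sz]))
        pts = np.array(pts)
        coords = (pts - np.asarray(grid.origin)) / np.asarray(grid.spacing)
        vals = map_coordinates(corr.g[0], coords.T, order=1, mode="grid-wrap")
        assert np.ptp(vals) < 1e-6

        # random equal-radius directions agree up to trilinear error only
        rng = np.random.default_rng(7)
        dirs = rng.standard_normal((40, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        coords = (4.0 * dirs - np.asarray(grid.origin)) / np.asarray(grid.spacing)
        vals = map_coordinates(corr.g[0], coords.T, order=1, mode="grid-wrap")
        # bound set by trilinear error on the 0.5 Å grid, not by the solver
        assert np.ptp(vals) < 0.1 * max(1.0, np.abs(vals).max())

    def test_kh_branch_regions(self, lj_fixture, sus_kh, thermo, coarse_config):
        grid = build_grid(lj_fixture.solute, 8.0, 0.5)
        pots = solute_site_potentials(lj_fixture.solute, _solvent_sites(sus_kh), grid)
        corr = solve_3drism(pots, sus_kh, ClosureSpec("KH"), thermo=thermo, tol=1e-7)
        t_star = -thermo.beta * corr.u + corr.h - corr.c
        g = corr.g
        linear = g > 1.0
        assert np.allclose(g[linear], 1.0 + t_star[linear], atol=1e-9)
        exp_region = g <= 1.0
        safe = exp_region & (t_star > -200.0)
        assert np.allclose(g[safe], np.exp(t_star[safe]), atol=1e-9)

    def test_repulsive_core_excluded_volume(self, sus_pse3, thermo):
        # purely repulsive solute: h <= 0 inside the core
        solute = SoluteModel(("Ne",), np.zeros((1, 3)), (Site("Ne", 0.0, 3.0, 0.3),))
        grid = build_grid(solute, 8.0, 0.5)
        pots = solute_site_potentials(solute, _solvent_sites(sus_pse3), grid)
        corr = solve_3drism(pots, sus_pse3, ClosureSpec("KH"), thermo=thermo)
        x, y, z = grid.axes()
        r2 = x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
        core = r2 < (0.8 * 3.0) ** 2
        assert np.all(corr.h[:, core] <= 1e-10)

    def test_boundary_bulk_like(self, dipolar_fixture, sus_pse3, thermo):
        grid = build_grid(dipolar_fixture.solute, 15.0, 0.6)
        pots = solute_site_potentials(
            dipolar_fixture.solute, _solvent_sites(sus_pse3), grid
        )
        corr = solve_3drism(pots, sus_pse3, ClosureSpec("PSE", 3), thermo=thermo)
        g = corr.g
        for face in (g[:, 0], g[:, -1], g[:, :, 0], g[:, :, -1],
                     g[:, :, :, 0], g[:, :, :, -1]):
            assert np.max(np.abs(face - 1.0)) < 5e-3

    def test_site_mismatch_rejected(self, lj_fixture, sus_pse3, thermo):
        grid = build_grid(lj_fixture.solute, 5.0, 1.0)
        pots = solute_site_potentials(lj_fixture.solute, [Site("Q", 0.0, 3.0, 0.2)], grid)
        with pytest.raises(ValueError, match="do not match"):
            solve_3drism(pots, sus_pse3, ClosureSpec("KH"), thermo=thermo)

    def test_g_nonnegative_everywhere(self, dipolar_solution):
        corr, _ = dipolar_solution
        assert np.all(corr.g >= 0.0)

    def test_tolerance_invariance_of_free_energy(self, lj_fixture, sus_pse3, thermo,
                                                 coarse_config):
        from ecrism.driver import solvate_once
        from dataclasses import replace

        _, rep1 = solvate_once(lj_fixture.solute, coarse_config, sus_pse3)
        tighter = replace(coarse_config, rism_tol=coarse_config.rism_tol / 2.0)
        _, rep2 = solvate_once(lj_fixture.solute, tighter, sus_pse3)
        assert abs(rep1.delta_g["PSE-3"] - rep2.delta_g["PSE-3"]) < 0.01
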