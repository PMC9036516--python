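import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecrism import constants
from ecrism.charges import (
    BONDI_RADII,
    SAMPL6_RADII,
    AtomicCharges,
    ChargeMap,
    ESPSample,
    chelpg_points,
    drop_small,
    fit_esp_charges,
    load_radii_table,
    mk_points,
    point_charge_esp,
    solvent_charge_map,
)
from ecrism.fixtures import direct_esp, make_fixture, naive_constrained_lsq
from ecrism.forcefield import Site, SoluteModel


def _atom(element="Ar", pos=(0.0, 0.0, 0.0)):
    return SoluteModel((element,), np.array([pos]), (Site(element, 0.0, 3.4, 1.0),))


class TestChelpgPoints:
    def test_single_atom_count_matches_brute_enumeration(self):
        solute = _atom()
        radius = BONDI_RADII["Ar"]
        pts = chelpg_points(solute, shell_spacing=1.0, r_max=2.8)
        # independent enumeration over the same centered lattice
        count = 0
        for i in range(-10, 11):
            for j in range(-10, 11):
                for k in range(-10, 11):
                    r = np.linalg.norm([i, j, k])
                    if radius <= r <= 2.8:
                        count += 1
        assert len(pts) == count

    def test_mirror_symmetry(self):
        solute = SoluteModel(
            ("C", "O"), np.array([[0.7, 0.2, -0.3], [-0.9, 0.1, 0.4]]),
            (Site("C", 0.0, 3.4, 0.5), Site("O", 0.0, 3.0, 0.6)),
        )
        mirrored = SoluteModel(
            solute.elements, solute.positions * np.array([-1.0, 1.0, 1.0]),
            solute.sites,
        )
        pts = chelpg_points(solute, shell_spacing=0.5)
        pts_m = chelpg_points(mirrored, shell_spacing=0.5)
        flipped = pts * np.array([-1.0, 1.0, 1.0])
        assert sorted(map(tuple, np.round(flipped, 9))) == sorted(
            map(tuple, np.round(pts_m, 9))
        )

    def test_points_outside_every_radius(self):
        fx = make_fixture("ammonia_like")
        pts = chelpg_points(fx.solute, shell_spacing=0.4)
        d = np.linalg.norm(pts[:, None, :] - fx.solute.positions[None, :, :], axis=-1)
        radii = np.array([BONDI_RADII[el] for el in fx.solute.elements])
        assert np.all(d >= radii[None, :] - 1e-12)
        assert np.all(d.min(axis=1) <= 2.8 + 1e-12)

    def test_degenerate_shell_signalled(self):
        with pytest.raises(ValueError, match="empty shell"):
            chelpg_points(_atom(), r_max=1.0)

    def test_missing_radius_names_element(self):
        solute = SoluteModel(("U",), np.zeros((1, 3)), (Site("U", 0.0, 3.0, 0.1),))
        with pytest.raises(KeyError, match="'U'"):
            chelpg_points(solute)

    def test_sampl6_br_variant(self):
        assert BONDI_RADII["Br"] == 1.75
        assert SAMPL6_RADII["Br"] == 1.30


def test_mk_points_on_shells():
    fx = make_fixture("dipolar_diatomic")
    pts = mk_points(fx.solute)
    d = np.linalg.norm(pts[:, None, :] - fx.solute.positions[None, :, :], axis=-1)
    radii = np.array([BONDI_RADII[el] for el in fx.solute.elements])
    assert np.all(d >= 1.4 * radii[None, :] - 1e-9)
    assert len(pts) > 50


def test_load_radii_table(tmp_path):
    p = tmp_path / "radii.txt"
    p.write_text("# custom radii\nC 1.7\nBr 1.3  # sampl6\n")
    table = load_radii_table(p)
    assert table == {"C": 1.7, "Br": 1.3}
    p.write_text("C 1.7 extra\n")
    with pytest.raises(ValueError, match="element radius"):
        load_radii_table(p)


class TestFitEspCharges:
    def test_exact_recovery_from_forward_model(self):
        positions = np.array([[0.0, 0.0, 0.7], [0.0, 0.0, -0.7]])
        truth = np.array([0.4, -0.4])
        rng = np.random.default_rng(3)
        pts = rng.uniform(-4, 4, size=(60, 3))
        pts = pts[np.linalg.norm(pts[:, None, :] - positions[None, :, :], axis=-1).min(axis=1) > 1.2]
        sample = ESPSample(pts, point_charge_esp(truth, positions, pts))
        fitted = fit_esp_charges(sample, positions, 0.0)
        assert fitted.values == pytest.approx(truth, abs=1e-10)
        assert fitted.rms_residual < 1e-12

    def test_total_charge_constraint(self, rng):
        positions = rng.uniform(-1, 1, size=(4, 3))
        pts = rng.uniform(-5, 5, size=(40, 3))
        pts = pts[np.linalg.norm(pts[:, None, :] - positions[None, :, :], axis=-1).min(axis=1) > 1.5]
        sample = ESPSample(pts, rng.standard_normal(len(pts)) * 0.01)
        fitted = fit_esp_charges(sample, positions, total_charge=-1.0)
        assert fitted.total == pytest.approx(-1.0, abs=1e-10)

    def test_symmetric_diatomic_gives_opposite_charges(self):
        positions = np.array([[0.0, 0.0, 0.8], [0.0, 0.0, -0.8]])
        truth = np.array([0.25, -0.25])
        zs = np.array([2.5, 3.0, -2.5, -3.0])
        pts = np.array([[0.0, 0.0, z] for z in zs] + [[2.0, 0.0, z] for z in zs])
        sample = ESPSample(pts, point_charge_esp(truth, positions, pts))
        fitted = fit_esp_charges(sample, positions, 0.0)
        assert fitted.values[0] == pytest.approx(-fitted.values[1], abs=1e-12)

    def test_too_few_points_signalled(self):
        positions = np.zeros((2, 3))
        positions[1, 2] = 1.0
        sample = ESPSample(np.array([[3.0, 0, 0], [0, 3.0, 0]]), np.zeros(2))
        with pytest.raises(ValueError, match="sample points"):
            fit_esp_charges(sample, positions, 0.0)

    def test_degenerate_geometry_signalled(self):
        # two coincident atoms produce an exactly collinear design matrix
        positions = np.zeros((2, 3))
        pts = np.random.default_rng(0).uniform(2, 4, size=(10, 3))
        sample = ESPSample(pts, np.zeros(10))
        with pytest.raises(np.linalg.LinAlgError, match="ill-conditioned"):
            fit_esp_charges(sample, positions, 0.0)

    def test_matches_naive_constrained_lsq_oracle(self):
        for seed in (1, 2, 3, 4, 5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 6))
            positions = rng.uniform(-1.5, 1.5, size=(n, 3))
            pts = rng.uniform(-6, 6, size=(50, 3))
            pts = pts[
                np.linalg.norm(pts[:, None, :] - positions[None, :, :], axis=-1).min(axis=1) > 2.0
            ]
            values = rng.standard_normal(len(pts)) * 0.05
            total = float(rng.uniform(-1, 1))
            sample = ESPSample(pts, values)
            fitted = fit_esp_charges(sample, positions, total)
            d = np.linalg.norm(pts[:, None, :] - positions[None, :, :], axis=-1)
            a = constants.BOHR_ANGSTROM / d
            oracle = naive_constrained_lsq(a, values, total)
            assert fitted.values == pytest.approx(oracle, abs=1e-9)

    def test_forward_model_matches_direct_esp_oracle(self):
        positions = np.array([[0.0, 0.0, 0.0]])
        pts = np.array([[1.0, 0.0, 0.0]])
        esp = point_charge_esp(np.array([1.0]), positions, pts)
        # one unit charge at 1 Å -> 1 / (1 Å in Bohr) hartree/e
        assert esp[0] == pytest.approx(constants.BOHR_ANGSTROM, rel=1e-12)
        assert esp == pytest.approx(direct_esp(np.array([1.0]), positions, pts), rel=1e-14)


class TestSolventChargeMap:
    def test_bulk_is_neutral(self, dipolar_solution):
        corr, _ = dipolar_solution
        cmap = solvent_charge_map(corr)
        # g = 1 voxels (far field) carry ~zero net charge for neutral water
        assert abs(cmap.total_charge) < 0.5  # net solvent polarization only
        bulk_subtracted = solvent_charge_map(corr, bulk_subtract=True)
        assert cmap.n_points == bulk_subtracted.n_points == corr.grid.n_voxels

    def test_uniform_g_gives_zero_charges(self):
        from ecrism.forcefield import ThermoState
        from ecrism.rism3d import Correlations3D, Grid3D

        dims = (4, 4, 4)
        grid = Grid3D((0.0, 0.0, 0.0), (0.5, 0.5, 0.5), dims)
        rho = 0.0333
        corr = Correlations3D(
            grid=grid, site_types=("O", "H"),
            site_densities=np.array([rho, 2 * rho]),
            site_charges=np.array([-0.8476, 0.4238]),
            thermo=ThermoState(), closure=None,
            u=np.zeros((2,) + dims), h=np.zeros((2,) + dims), c=np.zeros((2,) + dims),
        )
        cmap = solvent_charge_map(corr)
        assert np.allclose(cmap.charges, 0.0, atol=1e-18)

    def test_single_voxel_hand_computation(self):
        from ecrism.forcefield import ThermoState
        from ecrism.rism3d import Correlations3D, Grid3D

        dims = (3, 3, 3)
        grid = Grid3D((0.0, 0.0, 0.0), (0.5, 0.5, 0.5), dims)
        rho = 0.0333
        h = np.zeros((2,) + dims)
        h[0, 1, 1, 1] = 1.0  # g_O = 2 in one voxel
        corr = Correlations3D(
            grid=grid, site_types=("O", "H"),
            site_densities=np.array([rho, 2 * rho]),
            site_charges=np.array([-0.8476, 0.4238]),
            thermo=ThermoState(), closure=None,
            u=np.zeros((2,) + dims), h=h, c=np.zeros((2,) + dims),
        )
        cmap = solvent_charge_map(corr, bulk_subtract=True)
        expected = -0.8476 * rho * 0.125
        charges = cmap.charges.reshape(dims)
        assert charges[1, 1, 1] == pytest.approx(expected, rel=1e-12)
        charges[1, 1, 1] = 0.0
        assert np.allclose(charges, 0.0)

    def test_voxel_volume_linearity(self, dipolar_solution):
        corr, _ = dipolar_solution
        from dataclasses import replace

        doubled = replace(
            corr,
            grid=replace(
                corr.grid, spacing=tuple(2.0 * s for s in corr.grid.spacing)
            ),
        )
        c1 = solvent_charge_map(corr)
        c2 = solvent_charge_map(doubled)
        assert c2.charges == pytest.approx(8.0 * c1.charges, rel=1e-12)


class TestDropSmall:
    def test_zero_threshold_is_identity(self):
        m = ChargeMap(np.zeros((3, 3)), np.array([1e-8, 2e-5, -0.3]))
        out = drop_small(m, 0.0)
        assert np.array_equal(out.charges, m.charges)

    def test_all_dropped(self):
        m = ChargeMap(np.zeros((2, 3)), np.array([1e-8, -2e-8]))
        out = drop_small(m, 1.0)
        assert out.n_points == 0
        assert out.dropped_fraction == 1.0

    def test_counting_example(self):
        m = ChargeMap(np.zeros((3, 3)), np.array([1e-7, 5e-6, 2e-3]))
        out = drop_small(m, 1e-6)
        assert out.n_points == 2
        assert out.dropped_fraction == pytest.approx(1.0 / 3.0)

    def test_order_preserved(self):
        m = ChargeMap(
            np.arange(12, dtype=float).reshape(4, 3),
            np.array([0.5, 1e-9, -0.25, 0.125]),
        )
        out = drop_small(m, 1e-6)
        assert out.charges.tolist() == [0.5, -0.25, 0.125]
        assert out.points[1].tolist() == [6.0, 7.0, 8.0]

    @given(
        qs=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=30),
        thr=st.floats(0, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, qs, thr):
        m = ChargeMap(np.zeros((len(qs), 3)), np.array(qs))
        once = drop_small(m, thr)
        twice = drop_small(once, thr)
        assert np.array_equal(once.charges, twice.charges)
        assert twice.dropped_fraction == pytest.approx(once.dropped_fraction, abs=1e-15)

    def test_negative_threshold_rejected(self):
        m = ChargeMap(np.zeros((1, 3)), np.array([0.1]))
        with pytest.raises(ValueError):
            drop_small(m, -1e-6)
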