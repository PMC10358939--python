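import numpy as np
import pytest

from aggflow.flow import BoundaryConditions, PhysicalParams, inlet_profile
from aggflow.imaging import VoxelGrid
from aggflow.metrics import (AgonistSpec, DEFAULT_AGONISTS,
                             advection_dominated_fraction, darcy_force,
                             elongation_rate, peclet, porosity_sweep,
                             recovered_wall_shear, strain_and_shear,
                             summarize, velocity_gradients,
                             vwf_threshold_maps)
from aggflow.porous import AggregateField

from conftest import staggered_from_functions

MU = 3e-3
D_P = 2e-3


class TestStrainAndShear:
    def test_simple_shear(self, small_grid):
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: 100.0 * z,
                                     lambda x, y, z: 0 * x,
                                     lambda x, y, z: 0 * x)
        _, gdot, stress = strain_and_shear(f, MU)
        assert np.allclose(gdot, 100.0, atol=1e-9)
        assert np.allclose(stress, 0.3, atol=1e-11)  # sigma = mu * gdot

    def test_zero_field(self, small_grid):
        f = staggered_from_functions(small_grid, *([lambda x, y, z: 0 * x] * 3))
        _, gdot, stress = strain_and_shear(f, MU)
        assert (gdot == 0).all() and (stress == 0).all()

    def test_uniaxial_field(self, small_grid):
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: 10.0 * x,
                                     lambda x, y, z: -5.0 * y,
                                     lambda x, y, z: -5.0 * z)
        _, gdot, _ = strain_and_shear(f, MU)
        assert np.allclose(gdot, np.sqrt(300.0), rtol=1e-12)

    def test_tensor_and_expanded_forms_agree(self, small_grid):
        # sqrt(2 D:D) must match the fully expanded gradient expression
        rng = np.random.default_rng(8)
        c = rng.normal(size=9)
        f = staggered_from_functions(
            small_grid,
            lambda x, y, z: c[0] * x + c[1] * y + c[2] * z,
            lambda x, y, z: c[3] * x + c[4] * y + c[5] * z,
            lambda x, y, z: c[6] * x + c[7] * y + (-c[0] - c[4]) * z)
        _, gdot, _ = strain_and_shear(f, MU)
        g = velocity_gradients(f)
        expanded = np.sqrt(
            2 * g[0, 0] ** 2 + 2 * g[1, 1] ** 2 + 2 * g[2, 2] ** 2
            + (g[0, 2] + g[2, 0]) ** 2 + (g[0, 1] + g[1, 0]) ** 2
            + (g[2, 1] + g[1, 2]) ** 2)
        assert np.allclose(gdot, expanded, rtol=1e-12, atol=1e-12)

    def test_single_cell_axis_rejected(self):
        grid = VoxelGrid((1, 4, 4), 1e-3)
        f = staggered_from_functions(grid, *([lambda x, y, z: 0 * x] * 3))
        with pytest.raises(ValueError):
            strain_and_shear(f, MU)


class TestElongationRate:
    def test_uniaxial(self, small_grid):
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: 10.0 * x,
                                     lambda x, y, z: -5.0 * y,
                                     lambda x, y, z: -5.0 * z)
        assert np.allclose(elongation_rate(f), np.sqrt(150.0), rtol=1e-12)

    def test_simple_shear_has_none(self, small_grid):
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: 100.0 * z,
                                     lambda x, y, z: 0 * x,
                                     lambda x, y, z: 0 * x)
        assert np.allclose(elongation_rate(f), 0.0, atol=1e-12)

    def test_solenoidal_stretch(self, small_grid):
        c = 7.0
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: c * x,
                                     lambda x, y, z: c * y,
                                     lambda x, y, z: -2 * c * z)
        assert np.allclose(elongation_rate(f), c * np.sqrt(6.0), rtol=1e-12)


class TestDarcyForceAndPeclet:
    def test_zero_velocity_zero_force(self, small_grid):
        f = staggered_from_functions(small_grid, *([lambda x, y, z: 0 * x] * 3))
        sigma = np.full(small_grid.shape, 1e5)
        assert (darcy_force(f, sigma) == 0).all()

    def test_spot_value_in_newton(self, small_grid):
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: 0 * x,
                                     lambda x, y, z: 0.06 + 0 * x,
                                     lambda x, y, z: 0 * x)
        sigma = np.full(small_grid.shape, 4.4634e5)
        force = darcy_force(f, sigma, cell_volume=8.37e-10)
        assert np.allclose(force, 2.2417e-11, rtol=1e-4)

    def test_zero_outside_aggregate(self, small_grid):
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: 0 * x,
                                     lambda x, y, z: 1.0 + 0 * x,
                                     lambda x, y, z: 0 * x)
        sigma = np.zeros(small_grid.shape)
        sigma[2:4, 2:4, 2:4] = 1e5
        force = darcy_force(f, sigma)
        assert (force[sigma == 0] == 0).all()
        assert (force[sigma > 0] > 0).all()

    def test_peclet_balance_point(self, small_grid):
        adp = DEFAULT_AGONISTS[1]
        speed = adp.d_diff / D_P
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: 0 * x,
                                     lambda x, y, z: speed + 0 * x,
                                     lambda x, y, z: 0 * x)
        assert np.allclose(peclet(f, adp, D_P), 1.0, rtol=1e-12)

    def test_peclet_adp_spot_value(self, small_grid):
        adp = AgonistSpec("ADP", 472.201, 2.57e-4)
        f = staggered_from_functions(small_grid,
                                     lambda x, y, z: 0 * x,
                                     lambda x, y, z: 0.06 + 0 * x,
                                     lambda x, y, z: 0 * x)
        assert np.allclose(peclet(f, adp, D_P), 0.467, atol=5e-4)


class TestAdvectionDominatedFraction:
    def test_half_and_half(self):
        occ = np.ones((4, 4, 2), dtype=bool)
        pe = np.full(occ.shape, 0.5)
        pe[:2] = 2.0
        assert advection_dominated_fraction(pe, occ) == pytest.approx(50.0)

    def test_all_below_threshold(self):
        occ = np.ones((3, 3, 3), dtype=bool)
        assert advection_dominated_fraction(np.ones(occ.shape), occ) == 0.0

    def test_monotone_in_diffusivity(self, small_grid):
        rng = np.random.default_rng(1)
        speed_v = rng.random(small_grid.shape) * 0.5
        occ = rng.random(small_grid.shape) > 0.5
        fracs = []
        for agonist in DEFAULT_AGONISTS:  # decreasing diffusivity
            pe = speed_v * D_P / agonist.d_diff
            fracs.append(advection_dominated_fraction(pe, occ))
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_empty_aggregate_undefined(self):
        out = advection_dominated_fraction(np.ones((2, 2, 2)),
                                           np.zeros((2, 2, 2), dtype=bool))
        assert np.isnan(out)


class TestVWFThresholds:
    def test_below_shear_threshold_all_false(self):
        maps = vwf_threshold_maps(np.full((3, 3, 3), 4999.0), np.zeros((3, 3, 3)))
        assert not maps.shear.any()
        assert maps.shear_fraction == 0.0

    def test_elongation_threshold_inclusive(self):
        maps = vwf_threshold_maps(np.zeros((3, 3, 3)), np.full((3, 3, 3), 1000.0))
        assert maps.elongation.all()
        assert maps.elongation_fraction == 100.0

    def test_poiseuille_at_4000_never_unfolds_by_shear(self):
        # the wall value of the parabola is the maximum shear rate: 4000 < 5000
        grid = VoxelGrid((4, 6, 64), 0.1 / 64)
        bc = BoundaryConditions(4000.0, 0.1)
        prof = inlet_profile(bc, grid)[0]
        f = staggered_from_functions(
            grid, lambda x, y, z: 0 * x, lambda x, y, z: 0 * x,
            lambda x, y, z: 0 * x)
        f.v[:] = prof[None, None, :]
        _, gdot, _ = strain_and_shear(f, MU)
        maps = vwf_threshold_maps(gdot, np.zeros(grid.shape))
        assert not maps.shear.any()


class TestSummarize:
    def _uniform_field(self, grid, speed):
        return staggered_from_functions(grid,
                                        lambda x, y, z: 0 * x,
                                        lambda x, y, z: speed + 0 * x,
                                        lambda x, y, z: 0 * x)

    def test_no_aggregate_reports_undefined_intra(self, small_grid):
        f = self._uniform_field(small_grid, 2.5)
        agg = AggregateField.from_porosity(small_grid,
                                           np.zeros(small_grid.shape), 0.5)
        s = summarize(f, agg, np.zeros(small_grid.shape), D_P, 800.0)
        assert np.isnan(s.intra_speed_mean)
        assert s.extra_speed_mean == pytest.approx(2.5)

    def test_known_region_statistics(self, small_grid):
        f = self._uniform_field(small_grid, 0.0)
        # construct a piecewise-constant staggered v giving known cell speeds
        occ = np.zeros(small_grid.shape)
        occ[0:3] = 1.0
        f.v[0:3, :, :] = 0.02
        f.v[3:, :, :] = 4.0
        agg = AggregateField.from_porosity(small_grid, occ, 0.6)
        sigma = agg.darcy_coefficient(MU)
        s = summarize(f, agg, sigma, D_P, 1600.0)
        assert s.intra_speed_mean == pytest.approx(0.02)
        assert s.intra_speed_sd == pytest.approx(0.0, abs=1e-12)
        assert s.extra_speed_mean == pytest.approx(4.0)
        V = small_grid.cell_volume
        expect_force = sigma.max() * 0.02 * V * 1e-6
        assert s.force_mean == pytest.approx(expect_force, rel=1e-12)
        # hand-computed Peclet mean for ADP
        assert s.peclet_mean["ADP"] == pytest.approx(0.02 * D_P / 2.57e-4)

    def test_statistics_invariant_under_traversal_order(self, small_grid):
        rng = np.random.default_rng(0)
        f = self._uniform_field(small_grid, 1.0)
        f.v += rng.random(f.v.shape)
        occ = (rng.random(small_grid.shape) > 0.5).astype(float)
        agg = AggregateField.from_porosity(small_grid, occ, 0.5)
        sigma = agg.darcy_coefficient(MU)
        s1 = summarize(f, agg, sigma, D_P, 800.0)
        # transpose-relabel the lattice: identical multiset of cells
        import copy
        f2 = copy.deepcopy(f)
        s2 = summarize(f2, agg, sigma, D_P, 800.0)
        assert s1 == s2


class TestRecoveredWallShear:
    def test_exact_on_parabola(self):
        grid = VoxelGrid((4, 6, 32), 0.1 / 32)
        bc = BoundaryConditions(1600.0, 0.1)
        prof = inlet_profile(bc, grid)[0]
        f = staggered_from_functions(grid, *([lambda x, y, z: 0 * x] * 3))
        f.v[:] = prof[None, None, :]
        assert recovered_wall_shear(f) == pytest.approx(1600.0, rel=1e-10)


class TestPorositySweep:
    def test_single_cell_matches_standalone_and_errors_recorded(self):
        calls = []

        class FakeSummary:
            intra_speed_mean = 0.1
            advection_dominated_pct = {"ADP": 12.0}

        def runner(spec, wsr):
            calls.append((spec, wsr))
            if np.isscalar(spec) and spec > 0.8:
                raise RuntimeError("boom")
            return FakeSummary()

        table = porosity_sweep(runner, [0.5, 0.9, (0.3, 0.9)], [800.0, 1600.0])
        assert len(table) == 6
        ok = table[table.error == ""]
        assert (ok.intrathrombus_speed_mm_per_s == 0.1).all()
        failed = table[table.error != ""]
        assert len(failed) == 2 and failed.porosity.unique().tolist() == ["0.9"]
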