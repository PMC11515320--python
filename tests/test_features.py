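"""Operator stencils, feature assembly, scaling, and coordinate invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemopde.features import (
    ColumnScaler,
    DelaySpec,
    FeatureTable,
    arctan_observable,
    assemble_feature_matrix,
    divergence_radial,
    laplacian,
    operators_no_flux,
    radial_gradient,
    time_derivative,
)
from chemopde.simulate import RadialGrid, SpatioTemporalField


@pytest.fixture()
def grid():
    return RadialGrid.regular(50.0, 1.0)


@pytest.fixture()
def cart_grid():
    return RadialGrid.regular(50.0, 1.0, coordinate_mode="cartesian-1d")


class TestRadialGradient:
    def test_constant_is_zero(self, grid):
        np.testing.assert_allclose(radial_gradient(np.ones(grid.n), grid), 0.0, atol=1e-14)

    def test_linear_field(self, grid):
        g = radial_gradient(grid.r.copy(), grid)
        np.testing.assert_allclose(g[1:], 1.0, atol=1e-12)
        assert g[0] == 0.0  # symmetry value at the axis

    def test_quadratic_exact(self, grid):
        g = radial_gradient(grid.r**2, grid)
        np.testing.assert_allclose(g[1:], 2.0 * grid.r[1:], atol=1e-10)

    def test_too_few_points(self):
        tiny = RadialGrid(r=np.array([0.0, 1.0]), dr=1.0)
        with pytest.raises(ValueError):
            radial_gradient(np.zeros(2), tiny)


class TestLaplacian:
    def test_r_squared_cylindrical(self, grid):
        np.testing.assert_allclose(laplacian(grid.r**2, grid), 4.0, atol=1e-9)

    def test_r_squared_cartesian(self, cart_grid):
        np.testing.assert_allclose(laplacian(cart_grid.r**2, cart_grid), 2.0, atol=1e-9)

    def test_constant_zero_both_modes(self, grid, cart_grid):
        np.testing.assert_allclose(laplacian(np.ones(grid.n), grid), 0.0, atol=1e-12)
        np.testing.assert_allclose(laplacian(np.ones(cart_grid.n), cart_grid), 0.0, atol=1e-12)

    def test_linearity(self, grid, rng):
        u = rng.normal(size=grid.n)
        v = rng.normal(size=grid.n)
        lhs = laplacian(2.5 * u - 1.5 * v, grid)
        rhs = 2.5 * laplacian(u, grid) - 1.5 * laplacian(v, grid)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            RadialGrid(r=np.arange(5.0), dr=1.0, coordinate_mode="spherical")

    def test_convergence_order(self):
        """Observed order >= 2 on a smooth field under grid refinement."""
        errs = []
        for dr in (2.0, 1.0, 0.5):
            g = RadialGrid.regular(100.0, dr)
            u = np.exp(-(g.r**2) / (2 * 30.0**2))
            exact = (u / 30.0**2) * (g.r**2 / 30.0**2 - 2.0)
            err = np.abs(laplacian(u, g) - exact)[: g.n - 3].max()
            errs.append(err)
        order = np.log2(errs[0] / errs[1])
        assert order > 1.8
        order2 = np.log2(errs[1] / errs[2])
        assert order2 > 1.8

    def test_origin_excluded_grid(self):
        sub = RadialGrid(r=np.arange(10.0, 30.0, 1.0), dr=1.0)
        np.testing.assert_allclose(laplacian(sub.r**2, sub), 4.0, atol=1e-8)
        np.testing.assert_allclose(radial_gradient(sub.r**2, sub), 2 * sub.r, atol=1e-8)


class TestCoordinateConsistency:
    def test_cartesian_2d_embedding_matches_cylindrical(self):
        """Radially symmetric field on a 2-D Cartesian grid: the 5-point
        Laplacian along a ray agrees with the cylindrical-radial operator."""
        h = 0.5
        n = 161
        axis = (np.arange(n) - n // 2) * h
        X, Y = np.meshgrid(axis, axis, indexing="ij")
        R = np.hypot(X, Y)
        F = np.exp(-(R**2) / (2 * 8.0**2))
        lap2d = (
            np.roll(F, 1, 0) + np.roll(F, -1, 0) + np.roll(F, 1, 1) + np.roll(F, -1, 1) - 4 * F
        ) / h**2
        mid = n // 2
        ray_r = axis[mid : mid + 25]
        ray_lap = lap2d[mid, mid : mid + 25]
        grid = RadialGrid(r=ray_r, dr=h)
        prof = np.exp(-(grid.r**2) / (2 * 8.0**2))
        lap_cyl = laplacian(prof, grid)
        np.testing.assert_allclose(ray_lap[1:-2], lap_cyl[1:-2], rtol=0.02, atol=1e-4)


class TestDivergence:
    def test_linear_radial_field(self, grid):
        # div(r r̂) = 2 in cylindrical coordinates
        np.testing.assert_allclose(divergence_radial(grid.r.copy(), grid)[:-1], 2.0, atol=1e-9)


class TestTimeDerivative:
    def _field(self, vals, times, grid):
        return SpatioTemporalField(vals, times, grid, name="b")

    def test_constant_in_time(self, grid):
        times = np.arange(5.0)
        f = self._field(np.ones((5, grid.n)), times, grid)
        np.testing.assert_allclose(time_derivative(f, 1).values, 0.0, atol=1e-14)

    def test_linear_in_time(self, grid):
        times = np.arange(6.0)
        vals = 3.0 * times[:, None] * np.ones(grid.n)
        d = time_derivative(self._field(vals, times, grid), 1)
        np.testing.assert_allclose(d.values, 3.0, atol=1e-11)

    def test_quadratic_second_derivative(self, grid):
        times = np.arange(6.0)
        vals = times[:, None] ** 2 * np.ones(grid.n)
        d2 = time_derivative(self._field(vals, times, grid), 2)
        np.testing.assert_allclose(d2.values, 2.0, atol=1e-10)

    def test_nonuniform_times_rejected(self, grid):
        times = np.array([0.0, 1.0, 3.0])
        f = self._field(np.zeros((3, grid.n)), times, grid)
        with pytest.raises(ValueError, match="interpolate_time_rbf"):
            time_derivative(f, 1)

    def test_order_validation(self, grid):
        f = self._field(np.zeros((5, grid.n)), np.arange(5.0), grid)
        with pytest.raises(ValueError):
            time_derivative(f, 3)


class TestScaling:
    @given(
        st.integers(min_value=2, max_value=40),
        st.integers(min_value=1, max_value=5),
        st.sampled_from(["zscore", "minmax", "maxabs"]),
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip(self, n, d, kind):
        rng = np.random.default_rng(n * 7 + d)
        X = rng.normal(scale=3.0, size=(n, d)) + rng.uniform(-5, 5, size=d)
        sc = ColumnScaler(kind).fit(X)
        back = sc.inverse_transform(sc.transform(X))
        np.testing.assert_allclose(back, X, rtol=1e-12, atol=1e-9)

    def test_minmax_range(self, rng):
        X = rng.uniform(3.0, 9.0, size=(50, 2))
        Z = ColumnScaler("minmax").fit(X).transform(X)
        assert Z.min() >= -1.0 - 1e-12 and Z.max() <= 1.0 + 1e-12

    def test_maxabs_preserves_zero_and_sign(self, rng):
        X = rng.normal(size=(50, 1))
        sc = ColumnScaler("maxabs").fit(X)
        assert sc.transform(np.zeros((1, 1)))[0, 0] == 0.0
        assert np.all(np.sign(sc.transform(X)) == np.sign(X))

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            ColumnScaler("zscore").transform(np.zeros((2, 2)))


class TestArctanObservable:
    def test_axis_values(self):
        assert arctan_observable(1.0, 0.0) == pytest.approx(0.0)
        assert arctan_observable(1.0, 1.0) == pytest.approx(np.pi / 4)

    def test_singular_point_is_zero(self):
        assert arctan_observable(0.0, 0.0) == 0.0

    def test_sign_separation_on_wave(self, fast_sim):
        """Ahead/behind flat regions get opposite observable signs."""
        b, _, _ = fast_sim
        table = FeatureTable([b])
        k = int(np.argmin(np.abs(b.times - 250.0)))
        _, ri = b.window_indices(None, (0.0, 250.0))
        brow, grow = b.values[k][ri], table.arrays["grad_b"][k][ri]
        sc = ColumnScaler("maxabs").fit(np.column_stack([brow, grow]))
        z = sc.transform(np.column_stack([brow, grow]))
        o = arctan_observable(z[:, 0], z[:, 1])
        r = b.grid.r[ri]
        peak = r[np.argmax(brow)]
        flat = (np.abs(grow) < 0.01 * np.abs(grow).max()) & (np.abs(grow) > 0)
        good = np.concatenate([o[(r > peak) & flat] < 0, o[(r < peak) & flat] > 0])
        assert good.mean() > 0.95


class TestAssembly:
    def test_two_fields_six_columns(self, fast_sim):
        b, c, _ = fast_sim
        fm = assemble_feature_matrix([b, c], window=((200, 205), (0, 100)), stride=(2, 2))
        assert len(fm.columns) == 6
        assert fm.columns == ["b", "grad_b", "lap_b", "c", "grad_c", "lap_c"]
        assert np.all(np.isfinite(fm.X))

    def test_single_field_with_delay_six_columns(self, fast_sim):
        b, _, _ = fast_sim
        delay = DelaySpec(delta_t=b.report_dt)
        fm = assemble_feature_matrix([b], window=((200, 205), (0, 100)), delay=delay, stride=(2, 2))
        assert len(fm.columns) == 6
        assert fm.columns[3:] == ["b_lag1", "grad_b_lag1", "lap_b_lag1"]

    def test_empty_window_errors(self, fast_sim):
        b, c, _ = fast_sim
        with pytest.raises(ValueError, match="no samples"):
            assemble_feature_matrix([b, c], window=((1e4, 2e4), (0, 100)))

    def test_delay_not_multiple_rejected(self, fast_sim):
        b, _, _ = fast_sim
        with pytest.raises(ValueError, match="multiple"):
            FeatureTable([b], delay=DelaySpec(delta_t=0.3))

    def test_scaling_stats_stored(self, fast_sim):
        b, c, _ = fast_sim
        fm = assemble_feature_matrix([b, c], window=((200, 205), (0, 100)), stride=(3, 3))
        Z = fm.scaled()
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_lagged_rows_respect_delay(self, fast_sim):
        b, _, _ = fast_sim
        table = FeatureTable([b], delay=DelaySpec(delta_t=2 * b.report_dt))
        t_idx, r_idx = table.sample_indices(((200, 201), (0, 50)))
        X = table.extract(["b_lag1"], t_idx, r_idx)
        direct = b.values[np.ix_(t_idx - 2, r_idx)].ravel()
        np.testing.assert_allclose(X[:, 0], direct)


class TestNoFluxOperators:
    def test_zero_gradient_at_both_ends(self, grid, rng):
        u = rng.normal(size=grid.n)
        g, _ = operators_no_flux(u, grid)
        assert g[0] == 0.0 and g[-1] == 0.0

    def test_interior_matches_standard_stencils(self, grid, rng):
        u = rng.normal(size=grid.n)
        g, lap = operators_no_flux(u, grid)
        np.testing.assert_allclose(g[1:-1], radial_gradient(u, grid)[1:-1])
        np.testing.assert_allclose(lap[1:-1], laplacian(u, grid)[1:-1])
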