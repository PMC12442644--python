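import numpy as np
import pytest

from sgcd.containers import SpotTable
from sgcd.interpolation import (
    KernelParams,
    cauchy_kernel,
    fit_theta,
    gp_posterior,
    interpolate_slide,
    interpolation_weights,
    kernel_interpolate,
)
from sgcd.lattice import partition_gaps

from conftest import hex_lattice


def make_table(coords, expr):
    coords = np.asarray(coords, dtype=float)
    expr = np.asarray(expr, dtype=float)
    return SpotTable(expr=expr,
                     spot_ids=[f"s{i}" for i in range(len(coords))],
                     gene_ids=[f"g{j}" for j in range(expr.shape[1])],
                     coords=coords)


class TestCauchyKernel:
    def test_zero_distance(self):
        assert cauchy_kernel((3, 4), (3, 4), KernelParams(theta=2.0)) == 1.0

    def test_distance_sqrt_theta_gives_half(self):
        # ||xi - xj||^2 = theta -> 1 / (1 + 1) = 0.5
        assert cauchy_kernel((0, 0), (2, 0), KernelParams(theta=4.0)) == pytest.approx(0.5)

    def test_large_theta_limit(self):
        assert cauchy_kernel((0, 0), (1, 1), KernelParams(theta=1e12)) == pytest.approx(1.0, abs=1e-9)

    def test_theta_must_be_positive(self):
        with pytest.raises(ValueError):
            KernelParams(theta=0.0)


class TestInterpolationWeights:
    def test_single_point(self):
        w = interpolation_weights((0, 0), [(5, 5)], KernelParams(theta=1.0))
        np.testing.assert_allclose(w, [1.0])

    def test_two_equidistant(self):
        w = interpolation_weights((0, 0), [(1, 0), (-1, 0)], KernelParams(theta=1.0))
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_hand_arithmetic_two_thirds(self):
        # distances 0 and sqrt(theta): kernels (1, 0.5) -> weights (2/3, 1/3)
        w = interpolation_weights((0, 0), [(0, 0), (3, 0)], KernelParams(theta=9.0))
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_normalization_property(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.normal(size=(7, 2)) * 10
            w = interpolation_weights(rng.normal(size=2), pts, KernelParams(theta=3.0))
            assert np.all(w >= 0)
            assert abs(w.sum() - 1.0) < 1e-12

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            interpolation_weights((0, 0), np.empty((0, 2)), KernelParams(theta=1.0))


class TestKernelInterpolate:
    def test_constant_neighborhood(self):
        table = make_table([[0, 0], [1, 0], [0, 1]], np.tile([[2.0, -1.0]], (3, 1)))
        out = kernel_interpolate((0.4, 0.4), table, KernelParams(theta=1.0))
        np.testing.assert_allclose(out, [2.0, -1.0])

    def test_single_neighbor(self):
        table = make_table([[0, 0], [100, 100]], [[1.0, 2.0], [9.0, 9.0]])
        out = kernel_interpolate((0.1, 0.0), table, KernelParams(theta=1.0),
                                 neighborhood=1)
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_hand_weighted_combination(self):
        # weights (2/3, 1/3) on rows (3,0) and (0,3) -> (2,1)
        table = make_table([[0, 0], [3, 0]], [[3.0, 0.0], [0.0, 3.0]])
        out = kernel_interpolate((0, 0), table, KernelParams(theta=9.0))
        np.testing.assert_allclose(out, [2.0, 1.0], atol=1e-12)

    def test_convexity_invariant(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.uniform(0, 10, (12, 2)), rng.normal(size=(12, 5)))
        for _ in range(10):
            x = rng.uniform(0, 10, 2)
            out = kernel_interpolate(x, table, KernelParams(theta=5.0),
                                     neighborhood="all")
            assert np.all(out >= table.expr.min(axis=0) - 1e-12)
            assert np.all(out <= table.expr.max(axis=0) + 1e-12)


class TestGPPosterior:
    def test_mean_interpolates_training_points(self):
        # at a training coordinate the posterior collapses onto the value
        rng = np.random.default_rng(7)
        for _ in range(20):
            coords = rng.uniform(0, 10, size=(10, 2))
            values = rng.normal(size=(10, 3))
            i = rng.integers(10)
            post = gp_posterior(coords[i], coords, values, KernelParams(theta=4.0))
            np.testing.assert_allclose(post.mean, values[i], atol=1e-6)
            assert post.variance == pytest.approx(0.0, abs=1e-6)

    def test_far_away_reverts_to_prior(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        values = np.array([[5.0], [7.0]])
        post = gp_posterior((1e8, 1e8), coords, values, KernelParams(theta=1.0))
        np.testing.assert_allclose(post.mean, [0.0], atol=1e-6)
        assert post.variance == pytest.approx(1.0, abs=1e-6)

    def test_single_training_point_zero_distance(self):
        post = gp_posterior((2, 2), [(2, 2)], np.array([3.5]),
                            KernelParams(theta=1.0))
        np.testing.assert_allclose(post.mean, [3.5], atol=1e-9)
        assert post.variance == pytest.approx(0.0, abs=1e-9)

    def test_variance_non_increasing_in_training_points(self):
        # brute-force check on nested training sets
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 5, size=(8, 2))
        values = rng.normal(size=8)
        x_new = np.array([2.5, 2.5])
        prev = np.inf
        for n in range(1, 9):
            post = gp_posterior(x_new, coords[:n], values[:n],
                                KernelParams(theta=2.0))
            assert post.variance <= prev + 1e-9
            prev = post.variance

    def test_duplicate_points_resolved_by_jitter_ladder(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        values = np.array([1.0, 1.0, 2.0])
        post = gp_posterior((0.5, 0.5), coords, values, KernelParams(theta=1.0))
        assert np.isfinite(post.mean).all()


class TestFitTheta:
    def test_matches_brute_force_loo_oracle(self):
        rng = np.random.default_rng(2)
        coords = hex_lattice(4, 4, pitch=1.0)
        # smooth spatial field with known length scale + small noise
        field = np.sin(coords[:, 0] * 1.5) + np.cos(coords[:, 1] * 1.5)
        expr = np.column_stack([field, field**2]) + rng.normal(0, 0.01, (16, 2))
        table = make_table(coords, expr)
        grid = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
        chosen = fit_theta(table, grid).theta

        def loo_error(theta):
            total = 0.0
            for i in range(table.n_spots):
                others = np.ones(table.n_spots, bool)
                others[i] = False
                k = 1.0 / (1.0 + ((coords[others] - coords[i]) ** 2).sum(1) / theta)
                pred = (k / k.sum()) @ expr[others]
                total += ((pred - expr[i]) ** 2).sum()
            return total

        oracle = min(grid, key=loo_error)
        grid_sorted = sorted(grid)
        assert abs(grid_sorted.index(chosen) - grid_sorted.index(oracle)) <= 1

    def test_constant_field_ties_to_smallest(self):
        coords = hex_lattice(4, 3, pitch=1.0)
        table = make_table(coords, np.full((12, 2), 3.0))
        assert fit_theta(table, [5.0, 1.0, 2.0]).theta == 1.0

    def test_singleton_grid(self):
        coords = hex_lattice(4, 3, pitch=1.0)
        table = make_table(coords, np.random.default_rng(0).normal(size=(12, 2)))
        assert fit_theta(table, [0.7]).theta == 0.7

    def test_empty_grid_errors(self):
        coords = hex_lattice(4, 3, pitch=1.0)
        table = make_table(coords, np.ones((12, 2)))
        with pytest.raises(ValueError):
            fit_theta(table, [])


class TestInterpolateSlide:
    def test_zero_gaps_identity(self, tiny_table):
        out = interpolate_slide(tiny_table, [])
        np.testing.assert_array_equal(out.expr, tiny_table.expr)
        assert not out.is_interpolated.any()

    def test_constant_slide_stays_constant(self):
        coords = hex_lattice(4, 4)
        table = make_table(coords, np.full((16, 3), 1.5))
        gaps = partition_gaps(coords)
        out = interpolate_slide(table, gaps)
        assert out.n_spots == 16 + len(gaps)
        np.testing.assert_allclose(out.expr, 1.5)

    def test_original_rows_bit_identical_and_flagged(self):
        rng = np.random.default_rng(5)
        coords = hex_lattice(5, 5)
        table = make_table(coords, rng.normal(size=(25, 4)))
        gaps = partition_gaps(coords)
        out = interpolate_slide(table, gaps)
        np.testing.assert_array_equal(out.expr[:25], table.expr)
        assert not out.is_interpolated[:25].any()
        assert out.is_interpolated[25:].all()

    @pytest.mark.parametrize("mode", ["kernel", "gp"])
    def test_smooth_field_beats_global_mean(self, mode):
        # ground truth at gap centroids from the generating smooth field
        coords = hex_lattice(8, 8, pitch=1.0)
        def field(xy):
            return np.column_stack([np.sin(xy[:, 0]) * np.cos(xy[:, 1]),
                                    xy[:, 0] * 0.3 - xy[:, 1] * 0.2])
        table = make_table(coords, field(coords))
        gaps = partition_gaps(coords)
        out = interpolate_slide(table, gaps, mode=mode)
        truth = field(np.array([g.centroid for g in gaps]))
        pred = out.expr[out.is_interpolated]
        rmse = np.sqrt(((pred - truth) ** 2).mean())
        baseline = np.sqrt(((table.expr.mean(axis=0) - truth) ** 2).mean())
        assert rmse < baseline

    def test_coordinate_frame_mismatch_warns(self, tiny_table):
        from sgcd.lattice import GapRegion

        bad_gap = GapRegion((0, 1, 2), (500.0, 500.0))
        with pytest.warns(UserWarning, match="bounding box"):
            interpolate_slide(tiny_table, [bad_gap],
                              params=KernelParams(theta=1.0))
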