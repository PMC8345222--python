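"""Edge correction, Ripley's K, nearest neighbors, and scaled KDEs."""

import math

import numpy as np
import pytest

from geoihc.simulate import csr_pattern
from geoihc.spatial import (arc_fraction_inside, bivariate_k, eligibility,
                            kde2d_scaled, nn_distances, normalize_k,
                            spatial_positivity)
from geoihc.types import Intensity, Marker, PointPattern, Window
from .conftest import arc_fraction_oracle, make_roi, naive_bivariate_k


class TestArcFraction:
    def test_interior_circle(self, square_window):
        assert arc_fraction_inside((500, 500), 100, square_window) == pytest.approx(1.0)

    def test_center_on_edge(self, square_window):
        assert arc_fraction_inside((0, 500), 50, square_window) == pytest.approx(0.5)

    def test_center_at_corner(self, square_window):
        assert arc_fraction_inside((0, 0), 50, square_window) == pytest.approx(0.25)

    def test_matches_angular_sampling_oracle(self, rng):
        window = Window(1719.852, 692.258)
        for _ in range(40):
            cx = rng.uniform(0, window.width)
            cy = rng.uniform(0, window.height)
            d = rng.uniform(1.0, 300.0)
            got = arc_fraction_inside((cx, cy), d, window)
            want = arc_fraction_oracle((cx, cy), d, window, n_angles=20000)
            assert got == pytest.approx(want, abs=1e-9)

    def test_rejects_nonpositive_radius(self, square_window):
        with pytest.raises(ValueError):
            arc_fraction_inside((10, 10), 0.0, square_window)

    def test_rejects_center_outside(self, square_window):
        with pytest.raises(ValueError):
            arc_fraction_inside((-5, 10), 1.0, square_window)


class TestBivariateK:
    def test_hand_worked_single_pair(self):
        # one interior pair 10 µm apart in a 10^6 µm² window at r = 25
        window = Window(1000, 1000)
        pf = PointPattern(np.array([[500.0, 500.0]]), window, Marker.ASMA)
        pt = PointPattern(np.array([[510.0, 500.0]]), window, Marker.KI67)
        est = bivariate_k(pf, pt, 25.0)
        assert est.k_hat == pytest.approx(1e6)
        assert est.nk == pytest.approx(1e6 / (math.pi * 625), rel=1e-12)
        assert est.pair_count == 1

    def test_no_pair_within_radius(self, square_window):
        pf = PointPattern(np.array([[100.0, 100.0]]), square_window, Marker.ASMA)
        pt = PointPattern(np.array([[900.0, 900.0]]), square_window, Marker.KI67)
        est = bivariate_k(pf, pt, 25.0)
        assert est.k_hat == 0.0 and est.nk == 0.0

    def test_univariate_excludes_self_pairs(self, square_window):
        pts = np.array([[500.0, 500.0], [510.0, 500.0]])
        pp = PointPattern(pts, square_window, Marker.ASMA)
        est = bivariate_k(pp, pp, 25.0)
        # two ordered interior pairs, weight 1 each, denominator n(n-1) = 2
        assert est.k_hat == pytest.approx(square_window.area)
        assert est.pair_count == 2

    def test_matches_naive_double_loop(self, rng):
        window = Window(400.0, 300.0)
        for k in range(8):
            nf = int(rng.integers(2, 50))
            nt = int(rng.integers(2, 50))
            pf = csr_pattern(nf, window, rng, Marker.ASMA)
            pt = csr_pattern(nt, window, rng, Marker.KI67)
            r = float(rng.uniform(10, 80))
            assert bivariate_k(pf, pt, r).k_hat == naive_bivariate_k(pf, pt, r)
            assert bivariate_k(pf, pf, r).k_hat == naive_bivariate_k(pf, pf, r)

    def test_k_nondecreasing_in_r(self, rng, square_window):
        pf = csr_pattern(60, square_window, rng, Marker.ASMA)
        pt = csr_pattern(60, square_window, rng, Marker.KI67)
        ks = [bivariate_k(pf, pt, r).k_hat for r in (10, 25, 50, 100, 200)]
        assert all(a <= b + 1e-9 for a, b in zip(ks, ks[1:]))

    def test_window_mismatch_and_bad_radius(self, rng, square_window):
        pf = csr_pattern(5, square_window, rng, Marker.ASMA)
        pt = csr_pattern(5, Window(500, 500), rng, Marker.KI67)
        with pytest.raises(ValueError):
            bivariate_k(pf, pt, 25.0)
        with pytest.raises(ValueError):
            bivariate_k(pf, pf, -1.0)

    def test_cross_type_coincident_pair_counts_once(self, square_window):
        pf = PointPattern(np.array([[500.0, 500.0]]), square_window, Marker.ASMA)
        pt = PointPattern(np.array([[500.0, 500.0]]), square_window, Marker.KI67)
        est = bivariate_k(pf, pt, 25.0)
        assert est.pair_count == 1 and est.k_hat == pytest.approx(square_window.area)


class TestNormalizeK:
    def test_definition_and_interpretation(self):
        assert normalize_k(math.pi * 625, 25.0) == pytest.approx(1.0)
        assert normalize_k(0.0, 25.0) == 0.0
        assert normalize_k(1.30 * math.pi * 625, 25.0) == pytest.approx(1.30)

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            normalize_k(1.0, 0.0)


class TestEligibility:
    @pytest.mark.parametrize("n,expected", [(10, True), (9, False), (0, False)])
    def test_threshold_inclusive(self, n, expected, rng, square_window):
        pp = csr_pattern(n, square_window, rng, Marker.KI67)
        assert eligibility(pp) is expected


class TestSpatialPositivity:
    def test_strong_only_rule(self, square_window):
        cells = ([(i * 10.0, 50.0, Marker.KI67, Intensity.STRONG) for i in range(5)]
                 + [(i * 10.0, 80.0, Marker.KI67, Intensity.WEAK) for i in range(7)]
                 + [(i * 10.0, 120.0, Marker.ASMA, Intensity.STRONG) for i in range(3)])
        roi = make_roi(cells, square_window)
        assert spatial_positivity(roi, Marker.KI67).n == 5
        assert spatial_positivity(roi, Marker.ASMA).n == 3

    def test_no_strong_cells_gives_empty_pattern(self, square_window):
        roi = make_roi([(10.0, 10.0, Marker.KI67, Intensity.WEAK)], square_window)
        assert spatial_positivity(roi, Marker.KI67).n == 0


class TestNNDistances:
    def test_symmetric_pair(self, square_window):
        a = PointPattern(np.array([[100.0, 100.0]]), square_window, Marker.ASMA)
        b = PointPattern(np.array([[100.0, 110.0]]), square_window, Marker.KI67)
        assert nn_distances(a, b).median == pytest.approx(10.0)
        assert nn_distances(b, a).median == pytest.approx(10.0)

    def test_minimum_of_candidates(self, square_window):
        a = PointPattern(np.array([[100.0, 100.0]]), square_window, Marker.ASMA)
        b = PointPattern(np.array([[105.0, 100.0], [108.0, 100.0],
                                   [120.0, 100.0]]), square_window, Marker.KI67)
        assert nn_distances(a, b).distances[0] == pytest.approx(5.0)

    def test_matches_exhaustive_scan(self, rng, square_window):
        pf = csr_pattern(120, square_window, rng, Marker.ASMA)
        pt = csr_pattern(90, square_window, rng, Marker.KI67)
        got = nn_distances(pf, pt).distances
        from scipy.spatial.distance import cdist
        want = cdist(pf.points, pt.points).min(axis=1)
        assert np.array_equal(got, want)

    def test_same_pattern_excludes_self(self, rng, square_window):
        pp = csr_pattern(50, square_window, rng, Marker.ASMA)
        got = nn_distances(pp, pp).distances
        assert np.all(got > 0)
        from scipy.spatial.distance import cdist
        d = cdist(pp.points, pp.points)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(got, d.min(axis=1))

    def test_empty_target_raises(self, rng, square_window):
        pf = csr_pattern(5, square_window, rng, Marker.ASMA)
        pt = PointPattern(np.empty((0, 2)), square_window, Marker.KI67)
        with pytest.raises(ValueError):
            nn_distances(pf, pt)


class TestKDE2D:
    def test_peak_scaled_to_one(self, rng):
        x = rng.exponential(20, 200)
        y = rng.exponential(35, 200)
        grid = kde2d_scaled(x, y, grid_n=64)
        assert grid.density.max() == pytest.approx(1.0)
        assert (grid.density >= 0).all()

    def test_two_separated_clusters_give_two_modes(self, rng):
        n = 150
        x = np.concatenate([rng.normal(10, 0.8, n), rng.normal(50, 0.8, n)])
        y = np.concatenate([rng.normal(10, 0.8, n), rng.normal(50, 0.8, n)])
        grid = kde2d_scaled(x, y, grid_n=128)
        gx, gy = np.meshgrid(grid.x_grid, grid.y_grid)
        near_a = grid.density[(np.hypot(gx - 10, gy - 10) < 5)]
        near_b = grid.density[(np.hypot(gx - 50, gy - 50) < 5)]
        far = grid.density[(np.hypot(gx - 30, gy - 30) < 5)]
        assert near_a.max() > 0.5 and near_b.max() > 0.5
        assert far.max() < 0.2
        assert grid.density.max() == pytest.approx(1.0)

    def test_degenerate_point_mass(self):
        grid = kde2d_scaled(np.full(10, 20.0), np.full(10, 30.0), grid_n=64)
        iy, ix = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        assert grid.x_grid[ix] == pytest.approx(20.0, abs=1.0)
        assert grid.y_grid[iy] == pytest.approx(30.0, abs=1.0)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            kde2d_scaled(np.array([1.0]), np.array([2.0]))

    def test_reports_axis_medians(self, rng):
        x = rng.uniform(0, 50, 99)
        y = rng.uniform(0, 80, 99)
        grid = kde2d_scaled(x, y)
        assert grid.x_median == pytest.approx(np.median(x))
        assert grid.y_median == pytest.approx(np.median(y))
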