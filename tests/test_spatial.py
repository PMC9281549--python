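"""Spatial weights, Moran's I, kernel density, polygon aggregation, comparison."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from opfe.errors import DegenerateInputError, InvalidInputError
from opfe.spatial import (
    aggregate_by_polygon,
    build_weights,
    compare_methods,
    counting_availability,
    kernel_density,
    morans_i,
    project_lonlat,
)


def brute_force_moran(values, w):
    """Independent double-loop evaluation of the Moran's I formula."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    s0 = w.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return (n / s0) * num / (z @ z).item()


class TestWeights:
    def test_inverse_distance_values(self):
        w = build_weights(np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert w.matrix[0, 1] == pytest.approx(0.5)
        assert w.matrix[0, 0] == 0.0

    def test_collinear_triplet(self):
        w = build_weights(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
        assert w.matrix[0, 2] == pytest.approx(0.5)
        assert w.matrix[0, 1] == pytest.approx(1.0)

    def test_coincident_pair_uses_distance_floor(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0]])
        w = build_weights(pts, min_distance=0.1)
        assert w.matrix[0, 1] == pytest.approx(10.0)

    def test_power_cutoff_and_row_standardization(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0]])
        w = build_weights(pts, power=2, cutoff=5.0)
        assert w.matrix[0, 1] == pytest.approx(0.25)
        assert w.matrix[0, 2] == 0.0
        rs = w.row_standardize()
        sums = rs.matrix.sum(axis=1)
        np.testing.assert_allclose(sums[sums > 0], 1.0)

    def test_symmetry_nonnegativity_zero_diagonal(self, rng):
        pts = rng.uniform(0, 100, (15, 2))
        w = build_weights(pts).matrix
        np.testing.assert_allclose(w, w.T)
        assert (w >= 0).all() and np.diag(w).sum() == 0

    def test_all_coincident_raises(self):
        with pytest.raises(DegenerateInputError):
            build_weights(np.zeros((3, 2)))


class TestMoransI:
    @pytest.mark.parametrize("n", [5, 10, 25])
    def test_null_expectation_closed_form(self, n, rng):
        pts = rng.uniform(0, 1000, (n, 2))
        res = morans_i(rng.normal(size=n), build_weights(pts))
        assert res["EI"] == pytest.approx(-1.0 / (n - 1))

    def test_agrees_with_brute_force_double_loop(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 50))
            pts = rng.uniform(0, 1000, (n, 2))
            vals = rng.normal(size=n)
            w = build_weights(pts)
            res = morans_i(vals, w)
            assert res["I"] == pytest.approx(brute_force_moran(vals, w.matrix), abs=1e-10)

    def test_checkerboard_is_negatively_autocorrelated(self):
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        vals = np.array([(-1.0) ** (i + j) for i, j in zip(xs.ravel(), ys.ravel())])
        res = morans_i(vals, build_weights(pts, min_distance=0.01))
        assert res["I"] < res["EI"]

    def test_two_clusters_positive_and_significant_by_permutation(self, rng):
        a = rng.normal(0, 0.1, (15, 2))
        b = rng.normal(0, 0.1, (15, 2)) + 1000.0
        pts = np.vstack([a, b])
        vals = np.concatenate([rng.normal(10, 1, 15), rng.normal(-10, 1, 15)])
        res = morans_i(vals, build_weights(pts), method="permutation", seed=7)
        assert res["I"] > 0
        assert res["p"] < 0.05

    def test_permutation_p_is_seeded(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        vals = rng.normal(size=20)
        w = build_weights(pts)
        r1 = morans_i(vals, w, method="permutation", seed=3)
        r2 = morans_i(vals, w, method="permutation", seed=3)
        assert r1 == r2

    def test_constant_values_raise(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        with pytest.raises(DegenerateInputError):
            morans_i(np.ones(10), build_weights(pts))


class TestKernelDensity:
    def test_single_point_mass_conserved(self):
        surf = kernel_density(np.array([[0.0, 0.0]]), [1.0], cell_size=5.0, bandwidth=100.0)
        assert surf.integrate() == pytest.approx(1.0, rel=0.02)

    def test_linearity_in_weights(self, rng):
        pts = rng.uniform(0, 500, (20, 2))
        s1 = kernel_density(pts, np.ones(20), cell_size=10.0, bandwidth=150.0)
        s2 = kernel_density(pts, 2 * np.ones(20), cell_size=10.0, bandwidth=150.0)
        np.testing.assert_allclose(s2.grid, 2 * s1.grid)

    def test_duplicate_point_equals_double_weight(self):
        p = np.array([[100.0, 100.0]])
        dup = kernel_density(np.vstack([p, p]), [1.0, 1.0], cell_size=10.0, bandwidth=80.0)
        dbl = kernel_density(p, [2.0], cell_size=10.0, bandwidth=80.0)
        np.testing.assert_allclose(dup.grid, dbl.grid)

    def test_total_mass_matches_weight_sum(self, rng):
        pts = rng.uniform(0, 300, (30, 2))
        wts = rng.uniform(0.5, 4.0, 30)
        surf = kernel_density(pts, wts, cell_size=5.0, bandwidth=100.0)
        assert surf.integrate() == pytest.approx(wts.sum(), rel=0.02)

    def test_argmax_at_the_heavy_point(self):
        pts = np.array([[0.0, 0.0], [500.0, 500.0]])
        surf = kernel_density(pts, [1.0, 10.0], cell_size=10.0, bandwidth=100.0)
        x, y = surf.argmax_xy()
        assert abs(x - 500) <= 10 and abs(y - 500) <= 10

    def test_invalid_bandwidth_raises(self):
        with pytest.raises(InvalidInputError):
            kernel_density(np.array([[0.0, 0.0]]), [1.0], bandwidth=-5.0)

    def test_asc_roundtrip_header(self, tmp_path):
        surf = kernel_density(np.array([[0.0, 0.0]]), [1.0], cell_size=30.0, bandwidth=90.0)
        path = tmp_path / "kde.asc"
        surf.write_asc(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("ncols") and lines[4].startswith("cellsize 30")
        grid = np.loadtxt(lines[6:])
        np.testing.assert_allclose(grid, surf.grid)


def square(x0, y0, size=10.0):
    return Polygon([(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)])


@pytest.fixture
def outlet_frame():
    return pd.DataFrame(
        {
            "x": [1.0, 5.0, 15.0, 10.0, 40.0],
            "y": [1.0, 5.0, 5.0, 5.0, 5.0],
            "category": ["1-1", "1-2", "1-1", "1-1", "1-2"],
            "z_TUHII": [1.0, 2.0, 3.0, 4.0, 5.0],
            "W": [1.0, 0.5, 0.2, 1.0, 0.0],
        }
    )


class TestPolygonAggregation:
    def test_conservation_single_polygon(self, outlet_frame):
        polys = [("A", square(0, 0, 100))]
        summary = aggregate_by_polygon(outlet_frame, polys)
        assert summary["sum_z_TUHII"].sum() == pytest.approx(outlet_frame["z_TUHII"].sum())
        assert summary["count"].sum() == len(outlet_frame)

    def test_boundary_point_goes_to_first_polygon(self, outlet_frame):
        polys = [("A", square(0, 0)), ("B", square(10, 0)), ("C", square(30, 0, 20))]
        summary = aggregate_by_polygon(outlet_frame, polys)
        a = summary[summary["polygon_id"] == "A"]
        # the outlet at x=10 sits on the A|B boundary and must land in A
        assert a["count"].sum() == 3

    def test_outside_points_go_to_unassigned_with_warning(self, outlet_frame):
        polys = [("A", square(0, 0))]
        with pytest.warns(UserWarning):
            summary = aggregate_by_polygon(outlet_frame, polys)
        # x=15 and x=40 fall outside A=[0,10]^2; x=10 is on A's boundary
        assert summary[summary["polygon_id"] == "unassigned"]["count"].sum() == 2
        assert summary["count"].sum() == len(outlet_frame)

    def test_empty_polygon_zero_rows(self, outlet_frame):
        polys = [("A", square(0, 0, 100)), ("EMPTY", square(1000, 1000))]
        summary = aggregate_by_polygon(outlet_frame, polys)
        assert "EMPTY" not in set(summary["polygon_id"])


class TestCountingAndComparison:
    def test_subset_counts_conserve(self, outlet_frame):
        polys = [("A", square(0, 0)), ("B", square(10, 0)), ("C", square(30, 0, 20))]
        healthy = counting_availability(outlet_frame, polys, subset="healthy")
        assert healthy["count"].sum() == (outlet_frame["W"] == 1.0).sum()
        allc = counting_availability(outlet_frame, polys, subset="all")
        unhealthy = counting_availability(outlet_frame, polys, subset="unhealthy")
        assert (allc["count"] == healthy["count"] + unhealthy["count"]).all()

    def test_two_polygon_z_counts(self):
        df = pd.DataFrame(
            {"x": [1.0] * 2 + [15.0] * 8, "y": [5.0] * 10, "W": [0.0] * 10}
        )
        polys = [("A", square(0, 0)), ("B", square(10, 0))]
        res = counting_availability(df, polys, subset="all").set_index("polygon_id")
        np.testing.assert_allclose(
            res["z_count"], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_single_polygon_z_undefined(self, outlet_frame):
        with pytest.warns(UserWarning):
            res = counting_availability(outlet_frame, [("A", square(0, 0, 100))], "all")
        assert res["z_count"].isna().all()

    @pytest.mark.parametrize(
        "a,b,rho",
        [
            ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_spearman_hand_cases(self, a, b, rho):
        assert compare_methods(a, b)["rho"] == pytest.approx(rho)

    def test_degenerate_comparison_raises(self):
        with pytest.raises(DegenerateInputError):
            compare_methods([1, 1, 1, 1], [1, 2, 3, 4])


class TestProjection:
    def test_local_metric_distances_match_geodesy(self):
        # ~1 km east and north of the centroid at Beijing's latitude
        lon = np.array([116.30, 116.30 + 0.011692])
        lat = np.array([39.90, 39.90])
        x, y = project_lonlat(lon, lat)
        d = np.hypot(np.diff(x), np.diff(y))[0]
        assert d == pytest.approx(1000.0, rel=0.01)
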