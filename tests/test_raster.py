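"""Raster model: gridding, void filling, CHM differencing, clipping, I/O."""

import numpy as np
import pytest
import shapely

import chmstand as cs
from chmstand.raster import (
    read_ascii_grid,
    read_point_cloud_csv,
    read_stand_geojson,
    write_ascii_grid,
    write_point_cloud_csv,
    write_stand_geojson,
)


class TestGridding:
    def test_single_point_fills_one_cell(self):
        cloud = cs.PointCloud([0.25], [0.25], [5.0])
        r = cs.grid_points_to_dsm(cloud, 0.5)
        assert r.values[r.cell_index(0.25, 0.25)] == 5.0
        assert np.isnan(r.values).sum() == r.values.size - 1

    def test_max_rule_within_cell(self):
        cloud = cs.PointCloud([0.1, 0.2], [0.1, 0.2], [5.0, 7.0])
        r = cs.grid_points_to_dsm(cloud, 0.5)
        assert np.nanmax(r.values) == 7.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x, y, z = rng.uniform(0, 10, (3, 200))
        perm = rng.permutation(200)
        a = cs.grid_points_to_dsm(cs.PointCloud(x, y, z), 1.0)
        b = cs.grid_points_to_dsm(cs.PointCloud(x[perm], y[perm], z[perm]), 1.0)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_cloud_rejected(self):
        with pytest.raises(cs.RasterError):
            cs.grid_points_to_dsm(cs.PointCloud([], [], []), 0.5)

    def test_first_return_filter(self):
        cloud = cs.PointCloud([0.2, 0.2], [0.2, 0.2], [3.0, 9.0],
                              return_number=np.array([1, 2]))
        r = cs.grid_points_to_dsm(cloud, 0.5, first_return_only=True)
        assert np.nanmax(r.values) == 3.0

    def test_dense_sampling_round_trip(self):
        # smooth 20x20 surface sampled densely then regridded: cellwise match
        # within the gradient * cell-diagonal interpolation bound
        n, cell = 20, 1.0
        base = cs.Raster(np.zeros((n, n)), 0.0, n * cell, cell)
        xg, yg = base.center_grids()
        z = 0.2 * xg + 0.1 * yg + np.sin(xg / 4.0)
        surf = cs.Raster(z, 0.0, n * cell, cell)
        rng = np.random.default_rng(1)
        npts = 50 * n * n
        x = rng.uniform(0, n * cell, npts)
        y = rng.uniform(0, n * cell, npts)
        zs = surf.interpolate(x, y)
        regrid = cs.grid_points_to_dsm(cs.PointCloud(x, y, zs), cell)
        grad = 0.2 + 0.1 + 0.25  # max |dz/dx| + |dz/dy|
        bound = grad * cell * np.sqrt(2)
        common = np.abs(regrid.values[:n, :n] - surf.values)
        assert np.nanmax(common) <= bound


class TestFillVoids:
    def test_constant_neighborhood(self):
        v = np.full((3, 3), 2.0)
        v[1, 1] = np.nan
        filled = cs.fill_voids(cs.Raster(v))
        assert filled.values[1, 1] == pytest.approx(2.0)

    def test_no_voids_unchanged(self):
        v = np.arange(9.0).reshape(3, 3)
        filled = cs.fill_voids(cs.Raster(v))
        np.testing.assert_array_equal(filled.values, v)

    def test_linear_ramp_hand_value(self):
        # 5x5 ramp along columns; void at (2,2): mean of its 8 neighbors
        v = np.tile(np.arange(5.0), (5, 1))
        expected = np.mean([1, 2, 3, 1, 3, 1, 2, 3])
        v[2, 2] = np.nan
        filled = cs.fill_voids(cs.Raster(v))
        assert filled.values[2, 2] == pytest.approx(expected)

    def test_all_nodata_rejected(self):
        with pytest.raises(cs.RasterError):
            cs.fill_voids(cs.Raster(np.full((3, 3), np.nan)))

    def test_valid_cells_untouched(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 5, (8, 8))
        mask = rng.random((8, 8)) < 0.2
        v2 = v.copy()
        v2[mask] = np.nan
        filled = cs.fill_voids(cs.Raster(v2))
        np.testing.assert_array_equal(filled.values[~mask], v[~mask])
        assert not np.isnan(filled.values).any()


class TestCHM:
    def test_subtraction(self):
        dsm = cs.Raster(np.full((2, 2), 30.0))
        dtm = cs.Raster(np.full((2, 2), 10.0))
        assert np.all(cs.compute_chm(dsm, dtm).values == 20.0)

    def test_negative_clamped_to_zero(self):
        dsm = cs.Raster(np.full((2, 2), 9.9))
        dtm = cs.Raster(np.full((2, 2), 10.0))
        assert np.all(cs.compute_chm(dsm, dtm).values == 0.0)

    def test_nodata_propagates(self):
        dsm = cs.Raster(np.array([[np.nan, 30.0]]))
        dtm = cs.Raster(np.array([[10.0, 10.0]]))
        chm = cs.compute_chm(dsm, dtm)
        assert np.isnan(chm.values[0, 0]) and chm.values[0, 1] == 20.0

    def test_self_difference_is_zero(self):
        rng = np.random.default_rng(3)
        dsm = cs.Raster(rng.uniform(0, 50, (6, 6)))
        np.testing.assert_array_equal(cs.compute_chm(dsm, dsm).values, 0.0)

    def test_mismatched_cell_size_rejected(self):
        with pytest.raises(cs.RasterError):
            cs.compute_chm(
                cs.Raster(np.zeros((2, 2)), cell_size=1.0),
                cs.Raster(np.zeros((2, 2)), cell_size=2.0),
            )

    def test_shifted_dtm_resampled(self):
        # planar dtm shifted half a cell: bilinear resample keeps chm exact
        n = 6
        base = cs.Raster(np.zeros((n, n)), 0.0, n * 1.0, 1.0)
        xg, yg = base.center_grids()
        dsm = cs.Raster(0.5 * xg + 10.0, 0.0, float(n), 1.0)
        shifted = cs.Raster(np.zeros((n, n)), 0.5, float(n), 1.0)
        xs, ys = shifted.center_grids()
        dtm = cs.Raster(0.5 * xs, 0.5, float(n), 1.0)
        chm = cs.compute_chm(dsm, dtm)
        # interior columns are exactly 10; the west edge is extrapolated
        np.testing.assert_allclose(chm.values[:, 1:], 10.0, atol=1e-9)


class TestClip:
    def test_full_cover_identity(self):
        r = cs.Raster(np.ones((4, 4)), 0.0, 4.0, 1.0)
        poly = cs.StandPolygon(shapely.box(-1, -1, 5, 5))
        np.testing.assert_array_equal(cs.clip_to_polygon(r, poly).values, r.values)

    def test_half_plane_cell_centers(self):
        r = cs.Raster(np.ones((4, 4)), 0.0, 4.0, 1.0)
        poly = cs.StandPolygon(shapely.box(-1, -1, 2.0, 5))  # west half
        clipped = cs.clip_to_polygon(r, poly)
        # centers at x = 0.5, 1.5 inside; 2.5, 3.5 outside -> 8 cells retained
        assert clipped.valid_mask.sum() == 8
        assert clipped.valid_mask[:, :2].all()

    def test_idempotent(self):
        r = cs.Raster(np.ones((5, 5)), 0.0, 5.0, 1.0)
        poly = cs.StandPolygon(shapely.Polygon([(0, 0), (5, 0), (0, 5)]))
        once = cs.clip_to_polygon(r, poly)
        twice = cs.clip_to_polygon(once, poly)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_no_overlap_rejected(self):
        r = cs.Raster(np.ones((3, 3)), 0.0, 3.0, 1.0)
        with pytest.raises(cs.RasterError):
            cs.clip_to_polygon(r, cs.StandPolygon(shapely.box(10, 10, 12, 12)))

    def test_clipped_area_near_polygon_area(self):
        r = cs.Raster(np.ones((40, 40)), 0.0, 20.0, 0.5)
        poly = cs.StandPolygon(shapely.box(2.0, 2.0, 17.0, 17.0))
        clipped = cs.clip_to_polygon(r, poly)
        cell_area = 0.25
        raster_area = clipped.valid_mask.sum() * cell_area
        ring = poly.geometry.length * r.cell_size  # one cell-ring tolerance
        assert abs(raster_area - poly.area_m2) <= ring


class TestIO:
    def test_ascii_grid_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 40, (7, 5))
        v[2, 3] = np.nan
        r = cs.Raster(v, origin_x=3.5, origin_y=21.0, cell_size=0.5)
        p = tmp_path / "r.asc"
        write_ascii_grid(r, p)
        back = read_ascii_grid(p)
        assert back.cell_size == r.cell_size
        assert back.origin_x == pytest.approx(r.origin_x)
        assert back.origin_y == pytest.approx(r.origin_y)
        assert np.isnan(back.values[2, 3])
        np.testing.assert_allclose(back.values[~np.isnan(v)], v[~np.isnan(v)],
                                   atol=1e-5)

    def test_point_cloud_csv_round_trip(self, tmp_path):
        cloud = cs.PointCloud([1.0, 2.0], [3.0, 4.0], [5.0, 6.0])
        p = tmp_path / "pts.csv"
        write_point_cloud_csv(cloud, p)
        back = read_point_cloud_csv(p)
        np.testing.assert_array_equal(back.z, cloud.z)

    def test_stand_geojson_round_trip(self, tmp_path):
        poly = cs.StandPolygon(shapely.box(0, 0, 96.478, 96.478))
        p = tmp_path / "stand.geojson"
        write_stand_geojson(poly, p)
        back = read_stand_geojson(p)
        assert back.area_ha == pytest.approx(poly.area_ha)
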