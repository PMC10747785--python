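"""Allometry and stand aggregation: basal area, volume, carbon, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely

import chmstand as cs
from chmstand.metrics import register_volume_model

from conftest import cone_raster


class TestBasalArea:
    def test_unit_circle(self):
        assert cs.basal_area(100.0) == pytest.approx(math.pi / 4, abs=1e-4)

    def test_mean_dbh_evaluation(self):
        assert cs.basal_area(60.94) == pytest.approx(0.2917, abs=1e-4)

    def test_zero(self):
        assert cs.basal_area(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cs.basal_area(-1.0)

    def test_moment_identity_reproduces_stand_mean(self):
        # E[BA] = pi/4 (mu^2 + sd^2) for DBH mean 60.94, SD 7.14 -> 0.2957,
        # printing as the stand's 0.30 m2 mean
        mean_ba = math.pi / 4 * (0.6094**2 + 0.0714**2)
        assert mean_ba == pytest.approx(0.2957, abs=1e-4)
        assert round(mean_ba, 2) == 0.30


class TestStemVolume:
    def test_form_factor_evaluation(self):
        params = cs.AllometryParams(form_factor=0.36)
        assert cs.stem_volume(60.94, 35.2, params) == pytest.approx(3.696, abs=1e-3)

    def test_cylinder(self):
        params = cs.AllometryParams(form_factor=1.0)
        assert cs.stem_volume(100.0, 1.0, params) == pytest.approx(math.pi / 4)

    def test_linear_in_height(self):
        params = cs.AllometryParams()
        assert cs.stem_volume(50.0, 20.0, params) == pytest.approx(
            2 * cs.stem_volume(50.0, 10.0, params)
        )

    def test_injectable_model(self):
        register_volume_model("cube", lambda d, h, p: np.asarray(d, float) * 0 + 8.0)
        params = cs.AllometryParams(volume_model="cube")
        assert cs.stem_volume(10.0, 10.0, params) == 8.0

    def test_missing_model_rejected(self):
        params = cs.AllometryParams(volume_model="no_such_table")
        with pytest.raises(ValueError, match="no_such_table"):
            cs.stem_volume(10.0, 10.0, params)


class TestCarbonStock:
    def test_inventory_coefficients_mean_tree(self):
        # V·D·BEF·(1+R)·CF with larch defaults: 3.76 m3 -> 1.15 MgC
        cst = cs.carbon_stock(3.76)
        assert cst == pytest.approx(1.1493, abs=1e-3)
        assert round(cst, 2) == 1.15

    def test_zero_volume(self):
        assert cs.carbon_stock(0.0) == 0.0

    def test_unit_volume(self):
        assert cs.carbon_stock(1.0) == pytest.approx(0.3057, abs=1e-4)

    def test_linearity(self):
        a, b = 1.7, 2.9
        assert cs.carbon_stock(a + b) == pytest.approx(
            cs.carbon_stock(a) + cs.carbon_stock(b)
        )


class TestExtractHeights:
    def test_lookup_at_source_cell(self):
        chm = cone_raster(height=35.5, radius=4.0)
        tops = cs.detect_local_maxima(chm, search_radius=2.0)
        out = cs.extract_heights(chm, tops)
        assert out["height_m"].iloc[0] == chm.values[tops.row[0], tops.col[0]]

    def test_smoothing_never_raises_apex(self):
        chm = cone_raster(height=30.0, radius=5.0)
        smoothed = cs.apply_filter(chm, cs.FilterSpec("gaussian", 1.0))
        tops = cs.detect_local_maxima(smoothed, search_radius=2.0)
        h_smooth = cs.extract_heights(smoothed, tops)["height_m"].iloc[0]
        assert h_smooth <= np.nanmax(chm.values) + 1e-12

    def test_nodata_cell_rejected(self):
        chm = cone_raster()
        tops = cs.detect_local_maxima(chm, search_radius=2.0)
        v = chm.values.copy()
        v[tops.row[0], tops.col[0]] = np.nan
        with pytest.raises(ValueError, match="nodata"):
            cs.extract_heights(chm.copy(values=v), tops)

    def test_discretization_bound_on_stand(self, stand):
        """Extracted heights obey the crown-profile discretization bound
        err <= H (d/R)^a + tan(slope) d, and the 0.5 m figure for the crowns
        large enough to support it."""
        config, trees, chm = stand["config"], stand["trees"], stand["chm"]
        sm = cs.apply_filter(chm, cs.FilterSpec("lowpass", radius_or_sigma=1.0))
        tops = cs.detect_local_maxima(sm, search_radius=2.0)
        res = cs.match_treetops(
            np.column_stack([tops.x, tops.y]), tops.treetop_id,
            trees[["x", "y"]].to_numpy(), trees["tree_id"].to_numpy(),
            threshold=2.0,
        )
        heights = cs.extract_heights(chm, tops).set_index("treetop_id")["height_m"]
        tdx = trees.set_index("tree_id")
        d = config.cell_size * math.sqrt(2) / 2
        slope_term = math.tan(math.radians(config.terrain_slope_deg)) * d
        w = config.stand_width
        interior = 0
        for field_id, top_id, _ in res.matched_pairs:
            t = tdx.loc[field_id]
            if not (5 < t.x < w - 5 and 5 < t.y < w - 5):
                continue
            interior += 1
            err = abs(heights[top_id] - t.height_m)
            bound = (
                t.height_m
                * (d / t.crown_radius_m) ** config.crown_shape_exponent
                + slope_term
            )
            assert err <= bound + 1e-9
            if bound <= 0.5:
                assert err <= 0.5
        assert interior >= 50


class TestSummarize:
    def _poly(self, area_ha):
        side = math.sqrt(area_ha * 1e4)
        return cs.StandPolygon(shapely.box(0, 0, side, side))

    def test_per_ha_arithmetic(self):
        trees = pd.DataFrame(
            {"tree_id": [1, 2], "height_m": [30.0, 35.0], "dbh_cm": [50.0, 60.0]}
        )
        table = cs.tree_metrics_table(trees)
        table.loc[:, "volume_m3"] = [1.0, 2.0]
        table.loc[:, "carbon_MgC"] = cs.carbon_stock(table["volume_m3"].to_numpy())
        summary = cs.summarize_stand(table, self._poly(0.5))
        assert summary.volume_per_ha == pytest.approx(6.0)
        assert summary.density_stems_ha == pytest.approx(4.0)

    def test_single_tree_degenerate_moments(self):
        trees = pd.DataFrame({"tree_id": [1], "height_m": [30.0], "dbh_cm": [50.0]})
        summary = cs.summarize_stand(trees, self._poly(1.0))
        row = summary.stats.loc["height_m"]
        assert row["mean"] == row["min"] == row["max"] == 30.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.summarize_stand(pd.DataFrame(), self._poly(1.0))

    def test_aggregation_order_invariance(self):
        rng = np.random.default_rng(40)
        trees = pd.DataFrame(
            {
                "tree_id": np.arange(20),
                "height_m": rng.uniform(25, 42, 20),
                "dbh_cm": rng.uniform(45, 80, 20),
            }
        )
        poly = self._poly(0.93)
        summary = cs.summarize_stand(trees, poly)
        total_v = summary.volume_per_ha * poly.area_ha
        assert cs.carbon_stock(total_v) / poly.area_ha == pytest.approx(
            summary.carbon_per_ha
        )

    def test_moment_recovery_large_sample(self):
        # configured means recovered within 2 SE at n >= 300
        config = cs.SyntheticStandConfig(
            seed=41, stand_width=190.0, surface_noise_sd=0.0
        )
        trees = cs.generate_tree_list(config)
        assert len(trees) >= 500
        poly = config.stand_polygon
        summary = cs.summarize_stand(trees, poly)
        n = len(trees)
        for var, mu, sd in [
            ("height_m", config.height_mean, config.height_sd),
            ("dbh_cm", config.dbh_mean, config.dbh_sd),
        ]:
            se = sd / math.sqrt(n)
            # truncation pulls the height mean slightly toward the midpoint
            assert abs(summary.stats.loc[var, "mean"] - mu) <= 2 * se + 0.15
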