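"""Voronoi-tessellation crown delineation seeded at detected treetops.

Every valid CHM cell is a candidate for its nearest treetop (Euclidean
distance between cell center and seed).  A cell is kept in crown *i* iff

* its canopy height is at least ``exclusion`` times the seed height, and
* its distance to the seed is at most ``maxcrown`` times the seed height,

after which each crown is pruned to the 8-connected component containing its
seed cell, so crowns are physically contiguous.  Area is the retained cell
count times the cell area; perimeter is measured on the rasterized outline
(total exposed cell-edge length), which is biased high relative to a smoothed
hand-digitized boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.ops import unary_union

from .raster import Raster, StandPolygon
from .treetops import TreetopSet


@dataclass
class CrownSegment:
    """One delineated crown: raster cells, area, perimeter, outline polygon."""

    treetop_id: int
    cells: np.ndarray  # (n, 2) array of (row, col)
    area: float  # m^2
    perimeter: float  # m, rasterized outline
    polygon: shapely.Polygon | shapely.MultiPolygon | None = None


def _rasterized_perimeter(mask: np.ndarray, cell_size: float) -> float:
    """Total length of cell edges between the mask and its complement."""
    padded = np.pad(mask, 1, constant_values=False)
    exposed = 0
    exposed += np.sum(padded[1:, :] != padded[:-1, :])
    exposed += np.sum(padded[:, 1:] != padded[:, :-1])
    return float(exposed) * cell_size


def _cells_polygon(cells: np.ndarray, chm: Raster) -> shapely.Geometry:
    cs = chm.cell_size
    boxes = []
    for r, c in cells:
        x0 = chm.origin_x + c * cs
        y1 = chm.origin_y - r * cs
        boxes.append(shapely.box(x0, y1 - cs, x0 + cs, y1))
    return unary_union(boxes)


def delineate_crowns(
    chm: Raster,
    tops: TreetopSet,
    maxcrown: float = 0.4,
    exclusion: float = 0.7,
    build_polygons: bool = False,
) -> list[CrownSegment]:
    """Delineate one crown per treetop on the CHM.

    ``maxcrown`` bounds the crown radius as a fraction of the seed height;
    ``exclusion`` drops cells below that fraction of the seed height.
    """
    if len(tops) == 0:
        raise ValueError("no treetops to delineate crowns from")
    if not (0 < maxcrown <= 1):
        raise ValueError("maxcrown must be in (0, 1]")
    if not (0 <= exclusion < 1):
        raise ValueError("exclusion must be in [0, 1)")
    nrows, ncols = chm.shape
    oob = (tops.row < 0) | (tops.row >= nrows) | (tops.col < 0) | (tops.col >= ncols)
    if oob.any():
        bad = tops.treetop_id[oob]
        raise ValueError(f"treetop(s) outside raster: {list(bad)}")

    xg, yg = chm.center_grids()
    valid = chm.valid_mask
    # nearest-seed assignment (Voronoi in cell space)
    d2 = (
        (xg[None, :, :] - tops.x[:, None, None]) ** 2
        + (yg[None, :, :] - tops.y[:, None, None]) ** 2
    )
    nearest = np.argmin(d2, axis=0)
    dist_to_nearest = np.sqrt(np.take_along_axis(d2, nearest[None], axis=0)[0])

    crowns: list[CrownSegment] = []
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    for i in range(len(tops)):
        h = tops.chm_height[i]
        mask = (
            (nearest == i)
            & valid
            & (chm.values >= exclusion * h)
            & (dist_to_nearest <= maxcrown * h)
        )
        mask[tops.row[i], tops.col[i]] = True  # the seed always belongs
        labels, _ = ndimage.label(mask, structure=structure)
        seed_label = labels[tops.row[i], tops.col[i]]
        component = labels == seed_label
        cells = np.argwhere(component)
        crowns.append(
            CrownSegment(
                treetop_id=int(tops.treetop_id[i]),
                cells=cells,
                area=float(len(cells)) * chm.cell_size**2,
                perimeter=_rasterized_perimeter(component, chm.cell_size),
                polygon=_cells_polygon(cells, chm) if build_polygons else None,
            )
        )
    return crowns


def crown_cover(
    crowns: list[CrownSegment],
    poly: StandPolygon,
    subset: set | None = None,
) -> float:
    """Crown cover percentage: summed crown area over stand area, times 100.

    ``subset`` restricts the numerator to the given treetop ids.
    """
    if poly.area_m2 <= 0:
        raise ValueError("stand polygon area must be positive")
    total = sum(
        c.area for c in crowns if subset is None or c.treetop_id in subset
    )
    return 100.0 * total / poly.area_m2


def write_crowns_geojson(crowns: list[CrownSegment], chm: Raster, path) -> None:
    features = []
    for c in crowns:
        geom = c.polygon if c.polygon is not None else _cells_polygon(c.cells, chm)
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "treetop_id": c.treetop_id,
                    "area_m2": c.area,
                    "perimeter_m": c.perimeter,
                },
                "geometry": json.loads(shapely.to_geojson(geom)),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_manual_crowns_geojson(path) -> dict[int, float]:
    """Read externally digitized crown polygons; returns tree_id -> area m²."""
    with open(path) as fh:
        gj = json.load(fh)
    from shapely.geometry import shape as _shape

    out: dict[int, float] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        if "tree_id" not in props:
            raise ValueError("manual crown feature lacks a tree_id property")
        out[int(props["tree_id"])] = float(_shape(feat["geometry"]).area)
    return out
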