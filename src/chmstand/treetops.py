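"""Individual tree detection by local maxima on a (filtered) CHM.

A cell is a treetop iff its height is at least ``min_height`` and it is
strictly greater than every other valid cell inside its search neighborhood
(circular radius in meters, or a fixed square window in cells).  Plateau ties
are broken deterministically: among equal-valued cells that see each other,
only the one with the smallest (row, col) is reported, so a flat top yields
at most one detection.

The default ``min_height`` of 1.37 m is breast height — vegetation lower
than the DBH measurement height is not a tree for inventory purposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster, RasterError
from .smoothing import FilterSpec, apply_filter, disk_footprint

BREAST_HEIGHT_M = 1.37


@dataclass
class TreetopSet:
    """Detected local maxima: ids, planar coordinates, CHM heights, cells."""

    treetop_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    chm_height: np.ndarray
    row: np.ndarray
    col: np.ndarray

    def __len__(self) -> int:
        return len(self.treetop_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treetop_id": self.treetop_id,
                "x": self.x,
                "y": self.y,
                "chm_height": self.chm_height,
                "row": self.row,
                "col": self.col,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TreetopSet":
        return cls(
            treetop_id=df["treetop_id"].to_numpy(),
            x=df["x"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
            chm_height=df["chm_height"].to_numpy(dtype=float),
            row=df["row"].to_numpy(dtype=int),
            col=df["col"].to_numpy(dtype=int),
        )

    def to_geojson(self, path) -> None:
        import json

        features = [
            {
                "type": "Feature",
                "properties": {"treetop_id": int(i), "height": float(h)},
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            }
            for i, x, y, h in zip(self.treetop_id, self.x, self.y, self.chm_height)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def _neighborhood_footprint(
    chm: Raster,
    search_radius: float | None,
    fixed_window: int | None,
) -> np.ndarray:
    if (search_radius is None) == (fixed_window is None):
        raise ValueError("give exactly one of search_radius or fixed_window")
    if search_radius is not None:
        radius_cells = search_radius / chm.cell_size
        if radius_cells < 1.0:
            raise RasterError(
                f"search radius {search_radius} m is smaller than one cell "
                f"({chm.cell_size} m)"
            )
        return disk_footprint(radius_cells)
    if fixed_window % 2 == 0 or fixed_window < 3:
        raise ValueError("fixed_window must be odd and >= 3")
    return np.ones((fixed_window, fixed_window), dtype=bool)


def detect_local_maxima(
    chm: Raster,
    search_radius: float | None = None,
    fixed_window: int | None = None,
    min_height: float = BREAST_HEIGHT_M,
) -> TreetopSet:
    """Find treetop cells; coordinates are cell centers.

    Exactly one of ``search_radius`` (circular, meters) or ``fixed_window``
    (square, cells) selects the neighborhood.
    """
    footprint = _neighborhood_footprint(chm, search_radius, fixed_window)
    values = np.where(np.isnan(chm.values), -np.inf, chm.values)

    neigh = footprint.copy()
    neigh[footprint.shape[0] // 2, footprint.shape[1] // 2] = False
    # max over the neighborhood excluding the cell itself; -inf where empty
    nmax = ndimage.maximum_filter(
        values, footprint=neigh, mode="constant", cval=-np.inf
    )
    candidate = (chm.values >= min_height) & np.isfinite(chm.values)
    strict = candidate & (values > nmax)
    tied = candidate & (values == nmax)

    rows, cols = np.nonzero(strict | tied)
    keep_r, keep_c = [], []
    off_r, off_c = np.nonzero(neigh)
    off_r = off_r - footprint.shape[0] // 2
    off_c = off_c - footprint.shape[1] // 2
    nrows, ncols = chm.shape
    for r, c in zip(rows, cols):
        if strict[r, c]:
            keep_r.append(r)
            keep_c.append(c)
            continue
        # plateau: keep only if no equal-valued neighborhood cell precedes it
        v = values[r, c]
        first = True
        for dr, dc in zip(off_r, off_c):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and values[rr, cc] == v:
                if (rr, cc) < (r, c):
                    first = False
                    break
        if first:
            keep_r.append(r)
            keep_c.append(c)

    row = np.asarray(keep_r, dtype=int)
    col = np.asarray(keep_c, dtype=int)
    order = np.lexsort((col, row))
    row, col = row[order], col[order]
    x, y = chm.cell_center(row, col)
    return TreetopSet(
        treetop_id=np.arange(1, len(row) + 1),
        x=np.atleast_1d(x),
        y=np.atleast_1d(y),
        chm_height=chm.values[row, col],
        row=row,
        col=col,
    )


def detection_grid(
    chm: Raster,
    specs: list[tuple[FilterSpec | None, dict]],
    min_height: float = BREAST_HEIGHT_M,
) -> pd.DataFrame:
    """Run detection under a grid of (smoothing, neighborhood) settings.

    ``specs`` holds pairs of an optional :class:`FilterSpec` and the keyword
    arguments for :func:`detect_local_maxima` (``search_radius`` or
    ``fixed_window``).  Returns one row per setting with the treetop count.
    """
    if not specs:
        raise ValueError("detection grid needs at least one spec")
    rows = []
    for fspec, detect_kw in specs:
        smoothed = apply_filter(chm, fspec) if fspec is not None else chm
        tops = detect_local_maxima(smoothed, min_height=min_height, **detect_kw)
        rows.append(
            {
                "filter": fspec.label() if fspec is not None else "none",
                "search_radius_m": detect_kw.get("search_radius"),
                "fixed_window_cells": detect_kw.get("fixed_window"),
                "treetop_count": len(tops),
            }
        )
    return pd.DataFrame(rows)
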