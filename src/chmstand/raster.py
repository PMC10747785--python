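"""Raster data model, point-cloud gridding, CHM computation and clipping.

The raster convention throughout the package is north-up, row 0 northmost,
cell-center coordinates, 0-based row/col indices, half-open cell intervals
``[x, x + cell_size)``.  Missing cells are NaN in memory and written to disk
as the ``nodata`` sentinel (default -9999).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import shape as shapely_shape

DEFAULT_NODATA = -9999.0


class RasterError(ValueError):
    """Raised on invalid raster operations (mismatched grids, empty input...)."""


@dataclass
class Raster:
    """A single-band planar raster of heights in meters.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell heights; NaN marks nodata.
    origin_x, origin_y : float
        Top-left (north-west) corner of the grid in planar meters.
    cell_size : float
        Square cell edge length in meters.
    nodata : float
        Sentinel written to / read from disk in place of NaN.
    crs_label : str
        Free-text description of the planar coordinate system.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA
    crs_label: str = "local-meters"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("raster values must be a 2D array")
        if self.cell_size <= 0:
            raise RasterError("cell_size must be positive")
        # sentinel cells arriving from disk become NaN in memory
        self.values = np.where(self.values == self.nodata, np.nan, self.values)

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        """(x, y) of cell centers; row 0 is northmost."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_index(self, x: np.ndarray | float, y: np.ndarray | float):
        """(row, col) of the cells containing the points; half-open intervals."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.indices(self.shape)
        return self.cell_center(rows, cols)

    def copy(self, values: np.ndarray | None = None) -> "Raster":
        return replace(self, values=self.values.copy() if values is None else values)

    def interpolate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at arbitrary planar points.

        Points outside the cell-center hull are clamped to the edge value.
        """
        nrows, ncols = self.shape
        yc = self.origin_y - (np.arange(nrows) + 0.5) * self.cell_size
        xc = self.origin_x + (np.arange(ncols) + 0.5) * self.cell_size
        # rows run north->south, so the y axis is descending; flip for the
        # interpolator which requires ascending coordinates
        interp = RegularGridInterpolator(
            (yc[::-1], xc),
            self.values[::-1, :],
            method="linear",
            bounds_error=False,
            fill_value=None,
        )
        xq = np.clip(np.asarray(x, dtype=float), xc[0], xc[-1])
        yq = np.clip(np.asarray(y, dtype=float), yc[-1], yc[0])
        return interp(np.column_stack([np.ravel(yq), np.ravel(xq)])).reshape(
            np.shape(x)
        )


@dataclass
class PointCloud:
    """Parallel x/y/z arrays in planar meters, with an optional return number."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal lengths")
        if len(self.x) and not (
            np.isfinite(self.x).all()
            and np.isfinite(self.y).all()
            and np.isfinite(self.z).all()
        ):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class StandPolygon:
    """Simple planar polygon bounding the stand, with area in hectares."""

    geometry: shapely.Polygon

    def __post_init__(self) -> None:
        if not self.geometry.is_valid or self.geometry.is_empty:
            raise ValueError("stand polygon must be a valid non-empty polygon")
        if self.geometry.area <= 0:
            raise ValueError("stand polygon area must be positive")

    @classmethod
    def from_coords(cls, coords) -> "StandPolygon":
        return cls(shapely.Polygon(coords))

    @property
    def area_m2(self) -> float:
        return float(self.geometry.area)

    @property
    def area_ha(self) -> float:
        return float(self.geometry.area) / 10_000.0


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def grid_points_to_dsm(
    cloud: PointCloud,
    cell_size: float,
    first_return_only: bool = False,
) -> Raster:
    """Rasterize a point cloud by max-binning.

    Each cell takes the maximum z of the points falling in it; empty cells are
    nodata (use :func:`fill_voids` afterwards).  The extent is the point
    bounding box snapped outward to multiples of ``cell_size``.
    """
    if len(cloud) == 0:
        raise RasterError("cannot grid an empty point cloud")
    if cell_size <= 0:
        raise RasterError("cell_size must be positive")
    x, y, z = cloud.x, cloud.y, cloud.z
    if first_return_only and cloud.return_number is not None:
        keep = cloud.return_number == 1
        if not keep.any():
            raise RasterError("no first-return points in cloud")
        x, y, z = x[keep], y[keep], z[keep]

    origin_x = np.floor(x.min() / cell_size) * cell_size
    origin_y = np.ceil(y.max() / cell_size) * cell_size
    ncols = int(np.ceil((x.max() - origin_x) / cell_size)) or 1
    nrows = int(np.ceil((origin_y - y.min()) / cell_size)) or 1
    # points exactly on the east/south edge belong to the last cell
    col = np.clip(((x - origin_x) / cell_size).astype(int), 0, ncols - 1)
    row = np.clip(((origin_y - y) / cell_size).astype(int), 0, nrows - 1)

    values = np.full((nrows, ncols), -np.inf)
    np.maximum.at(values, (row, col), z)
    values[np.isinf(values)] = np.nan
    return Raster(values, origin_x=origin_x, origin_y=origin_y, cell_size=cell_size)


def fill_voids(r: Raster, max_iterations: int = 100) -> Raster:
    """Fill nodata cells by the iterated mean of their valid 8-neighbors.

    Valid cells are never modified.  Iteration stops when no fillable cell
    remains or ``max_iterations`` is reached; cells with no valid neighbor at
    any pass (isolated frame corners of an all-void region) stay nodata.
    """
    if not r.valid_mask.any():
        raise RasterError("cannot fill an all-nodata raster")
    values = r.values.copy()
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    for _ in range(max_iterations):
        invalid = np.isnan(values)
        if not invalid.any():
            break
        filled = np.nan_to_num(values)
        valid = (~invalid).astype(float)
        ssum = ndimage.convolve(filled * valid, kernel, mode="constant", cval=0.0)
        scount = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
        fillable = invalid & (scount > 0)
        if not fillable.any():
            break
        values[fillable] = ssum[fillable] / scount[fillable]
    return r.copy(values=values)


def _aligned(a: Raster, b: Raster) -> bool:
    return (
        a.shape == b.shape
        and np.isclose(a.origin_x, b.origin_x)
        and np.isclose(a.origin_y, b.origin_y)
    )


def compute_chm(dsm: Raster, dtm: Raster) -> Raster:
    """Canopy height model: DSM minus DTM, clamped below at zero.

    Negative differences (a photogrammetric surface dipping under the terrain)
    are not physical heights and are set to 0.  The DTM is bilinearly resampled
    onto the DSM grid when the origins differ; differing cell sizes are an
    error rather than a silent cross-resolution resample.
    """
    if not np.isclose(dsm.cell_size, dtm.cell_size):
        raise RasterError(
            f"cell sizes differ (dsm {dsm.cell_size} vs dtm {dtm.cell_size}); "
            "resample explicitly before differencing"
        )
    if _aligned(dsm, dtm):
        ground = dtm.values
    else:
        x, y = dsm.center_grids()
        ground = dtm.interpolate(x, y)
    chm = np.maximum(dsm.values - ground, 0.0)
    chm[np.isnan(dsm.values) | np.isnan(ground)] = np.nan
    return dsm.copy(values=chm)


def clip_to_polygon(r: Raster, poly: StandPolygon) -> Raster:
    """Set cells whose centers fall outside the polygon to nodata."""
    x, y = r.center_grids()
    inside = shapely.contains_xy(poly.geometry, x.ravel(), y.ravel()).reshape(r.shape)
    if not inside.any():
        raise RasterError("polygon does not overlap any raster cell center")
    values = np.where(inside, r.values, np.nan)
    return r.copy(values=values)


# ---------------------------------------------------------------------------
# I/O — plain-text formats
# ---------------------------------------------------------------------------


def write_ascii_grid(r: Raster, path) -> None:
    """Write an ESRI ASCII grid (xllcorner/yllcorner convention)."""
    nrows, ncols = r.shape
    yll = r.origin_y - nrows * r.cell_size
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {r.origin_x!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {r.cell_size!r}\n"
        f"NODATA_value {r.nodata!r}\n"
    )
    out = np.where(np.isnan(r.values), r.nodata, r.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6f")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:], ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise RasterError(f"grid body {values.shape} does not match header")
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    return Raster(
        values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=nodata,
    )


def read_point_cloud_csv(path) -> PointCloud:
    """Read a CSV with columns x,y,z (header optional)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if not {"x", "y", "z"} <= set(cols):
        # headerless: assume the first three columns are x, y, z
        df = pd.read_csv(path, header=None)
        df.columns = ["x", "y", "z"][: df.shape[1]] + list(df.columns[3:])
        cols = {c: c for c in ("x", "y", "z")}
    rn = None
    if "return_number" in cols:
        rn = df[cols["return_number"]].to_numpy(dtype=int)
    return PointCloud(
        df[cols["x"]].to_numpy(),
        df[cols["y"]].to_numpy(),
        df[cols["z"]].to_numpy(),
        return_number=rn,
    )


def write_point_cloud_csv(cloud: PointCloud, path) -> None:
    import pandas as pd

    pd.DataFrame({"x": cloud.x, "y": cloud.y, "z": cloud.z}).to_csv(path, index=False)


def read_stand_geojson(path) -> StandPolygon:
    """Read the first polygon feature of a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shapely_shape(gj["geometry"])]
    else:
        geoms = [shapely_shape(gj)]
    polys = [g for g in geoms if g.geom_type in ("Polygon", "MultiPolygon")]
    if not polys:
        raise ValueError(f"no polygon geometry in {path}")
    geom = polys[0]
    if geom.geom_type == "MultiPolygon":
        geom = max(geom.geoms, key=lambda g: g.area)
    return StandPolygon(geom)


def write_stand_geojson(poly: StandPolygon, path) -> None:
    feature = {
        "type": "Feature",
        "properties": {"area_ha": poly.area_ha},
        "geometry": json.loads(shapely.to_geojson(poly.geometry)),
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)
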