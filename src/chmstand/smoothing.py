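"""CHM smoothing filters: lowpass (circular mean), square mean, Gaussian.

All three are averaging filters computed by normalized convolution: nodata
cells are excluded from every average and stay nodata in the output, and at
raster edges the window shrinks to the valid in-bounds cells rather than
padding with invented values.  "Lowpass" follows the GIS convention of a
mean over a circular neighborhood; the square-window mean differs from it
only in neighborhood shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import Raster, RasterError

FILTER_METHODS = ("lowpass", "mean", "gaussian")


@dataclass(frozen=True)
class FilterSpec:
    """One smoothing configuration.

    method : 'lowpass' | 'mean' | 'gaussian'
    radius_or_sigma : circular radius (lowpass) or Gaussian sigma, in the
        declared unit.
    window : odd square window edge in cells (mean filter).
    unit : 'm' (converted to cells via the raster cell size) or 'cells'.
    """

    method: str
    radius_or_sigma: float | None = None
    window: int | None = None
    unit: str = "m"

    def __post_init__(self) -> None:
        if self.method not in FILTER_METHODS:
            raise ValueError(f"unknown filter method {self.method!r}")
        if self.method in ("lowpass", "gaussian"):
            if self.radius_or_sigma is None or self.radius_or_sigma <= 0:
                raise ValueError(f"{self.method} filter needs radius_or_sigma > 0")
        if self.method == "mean":
            if self.window is None:
                raise ValueError("mean filter needs a window size")
            if self.window % 2 == 0 or self.window < 3:
                raise ValueError("window must be odd and >= 3")
        if self.unit not in ("m", "cells"):
            raise ValueError("unit must be 'm' or 'cells'")

    def label(self) -> str:
        if self.method == "mean":
            return f"mean_w{self.window}"
        return f"{self.method}_{self.radius_or_sigma:g}{self.unit}"

    def in_cells(self, cell_size: float) -> float:
        """radius_or_sigma converted to cell units."""
        v = self.radius_or_sigma
        return v / cell_size if self.unit == "m" else float(v)


def disk_footprint(radius_cells: float) -> np.ndarray:
    """Boolean mask of cells whose centers lie within ``radius_cells`` of the
    center cell's center."""
    r = int(np.floor(radius_cells))
    if r < 1:
        return np.ones((1, 1), dtype=bool)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dx**2 + dy**2) <= radius_cells**2 + 1e-12


def gaussian_kernel(sigma_cells: float) -> np.ndarray:
    """Normalized Gaussian kernel truncated at 3 sigma."""
    r = max(int(round(3.0 * sigma_cells)), 0)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(dx**2 + dy**2) / (2.0 * sigma_cells**2))
    return k / k.sum()


def _normalized_convolve(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted mean over valid cells under the kernel; NaN-aware, edge-shrinking."""
    valid = ~np.isnan(values)
    filled = np.where(valid, values, 0.0)
    num = ndimage.convolve(filled * valid, weights, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), weights, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    out[den == 0] = np.nan
    return out


def apply_filter(chm: Raster, spec: FilterSpec) -> Raster:
    """Smooth a CHM according to ``spec``; grid geometry is unchanged."""
    if spec.method == "mean":
        weights = np.ones((spec.window, spec.window))
    elif spec.method == "lowpass":
        radius_cells = spec.in_cells(chm.cell_size)
        if radius_cells < 1.0:
            raise RasterError(
                f"lowpass radius {spec.radius_or_sigma} {spec.unit} is smaller "
                f"than one cell ({chm.cell_size} m)"
            )
        weights = disk_footprint(radius_cells).astype(float)
    else:  # gaussian
        sigma_cells = spec.in_cells(chm.cell_size)
        weights = gaussian_kernel(sigma_cells)
        if weights.shape == (1, 1):
            warnings.warn(
                f"gaussian sigma {spec.radius_or_sigma} {spec.unit} truncates to a "
                "single cell; filter is the identity",
                stacklevel=2,
            )
            return chm.copy()
    return chm.copy(values=_normalized_convolve(chm.values, weights))
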