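"""Shared fixtures: small rasters and a cached noise-free synthetic stand."""

from __future__ import annotations

import numpy as np
import pytest

import chmstand as cs


def cone_raster(
    height: float = 10.0,
    radius: float = 5.0,
    cell_size: float = 0.5,
    exponent: float = 1.0,
    pad: float = 2.0,
) -> cs.Raster:
    """A single crown profile z(r) = H·(1 − (r/R)^a) centered in the raster."""
    half = radius + pad
    n = int(np.ceil(2 * half / cell_size))
    r = cs.Raster(np.zeros((n, n)), 0.0, n * cell_size, cell_size)
    xg, yg = r.center_grids()
    cx = cy = n * cell_size / 2.0
    rr = np.hypot(xg - cx, yg - cy)
    z = np.maximum(height * (1.0 - (rr / radius) ** exponent), 0.0)
    return cs.Raster(z, 0.0, n * cell_size, cell_size)


@pytest.fixture(scope="session")
def stand():
    """A seeded noise-free calibration stand with surfaces and CHM."""
    config = cs.SyntheticStandConfig(seed=11, surface_noise_sd=0.0)
    trees = cs.generate_tree_list(config)
    dtm, dsm = cs.render_surfaces(trees, config)
    chm = cs.compute_chm(dsm, dtm)
    return {"config": config, "trees": trees, "dtm": dtm, "dsm": dsm, "chm": chm}
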