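"""Synthetic conifer stands with known ground truth.

The generator emulates an old single-species larch plantation on sloping
terrain: ~147 stems ha⁻¹ over ~0.93 ha, tree heights from a truncated normal
N(35.2, 3.27²) on [25.8, 42.9] m, DBH ~ N(60.94, 7.14²) cm correlated with
height, crown areas lognormal with mean 56.65 m² and SD 21.27 m², terrain a
planar ramp at 18–20°, rasters at 0.5 m.  Every downstream stage (gridding,
CHM, detection, crowns, allometry, regression) can then be tested by
recovering these known parameters.

Randomness: one integer seed drives a single ``numpy.random.default_rng``
stream, consumed in a fixed order — tree count, positions, heights, DBH
noise, crown areas, surface noise, point-cloud sampling — so identical
seed + config gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .metrics import AllometryParams, basal_area, carbon_stock, stem_volume
from .raster import PointCloud, Raster, StandPolygon


@dataclass(frozen=True)
class SyntheticStandConfig:
    """Study-condition parameters of the synthetic stand.

    Defaults reproduce the calibration stand: a 0.9308 ha square,
    147 stems ha⁻¹ with 3 m minimum spacing (old plantation after a century
    of self-thinning), truncated-normal heights, height-correlated DBH,
    lognormal crown areas, a 19° planar terrain ramp, and 0.5 m cells.
    """

    stand_width: float = 96.478  # m; square => 0.93 ha, the calibration area
    target_density: float = 147.0  # stems per ha
    min_spacing: float = 3.0  # m, hardcore distance
    height_mean: float = 35.2  # m
    height_sd: float = 3.27
    height_min: float = 25.8
    height_max: float = 42.9
    dbh_mean: float = 60.94  # cm
    dbh_sd: float = 7.14
    dbh_height_corr: float = 0.7
    crown_area_mean: float = 56.65  # m^2
    crown_area_sd: float = 21.27
    crown_shape_exponent: float = 2.0  # rounded (parabolic) conifer crown
    terrain_slope_deg: float = 19.0
    cell_size: float = 0.5  # m
    point_density: float = 40.0  # photogrammetric dense cloud, pts per m^2
    surface_noise_sd: float = 0.05  # m
    species: str = "larch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")
        if not (self.height_min < self.height_mean < self.height_max):
            raise ValueError("need height_min < height_mean < height_max")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.min_spacing < 0:
            raise ValueError("min_spacing cannot be negative")
        if min(self.height_sd, self.dbh_sd, self.crown_area_sd,
               self.surface_noise_sd) < 0:
            raise ValueError("standard deviations cannot be negative")

    @property
    def stand_polygon(self) -> StandPolygon:
        w = self.stand_width
        return StandPolygon(shapely.box(0.0, 0.0, w, w))

    def to_dict(self) -> dict:
        return asdict(self)


class PlacementError(RuntimeError):
    """Raised when the hardcore point process cannot satisfy min_spacing."""


def _place_trees(
    rng: np.random.Generator, config: SyntheticStandConfig, n: int
) -> np.ndarray:
    """Sequential-rejection hardcore placement of n points in the stand."""
    w = config.stand_width
    pts: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * max(n, 1)
    while len(pts) < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n} trees with min_spacing="
                f"{config.min_spacing} m in a {w:.1f} m square after "
                f"{max_attempts} attempts; density/min_spacing infeasible"
            )
        attempts += 1
        x, y = rng.uniform(0.0, w, size=2)
        if all(
            (x - px) ** 2 + (y - py) ** 2 >= config.min_spacing**2
            for px, py in pts
        ):
            pts.append((x, y))
    return np.asarray(pts)


def generate_tree_list(
    config: SyntheticStandConfig,
    allometry: AllometryParams = AllometryParams(),
) -> pd.DataFrame:
    """Draw a synthetic tree list with positions, heights, DBH and crowns.

    Tree count is Poisson(density × area); positions follow a hardcore
    (minimum-spacing) process; heights are truncated normal; DBH is linear in
    height with Gaussian residual, coefficients solved from the configured
    means/SDs and correlation; crown radii come from a lognormal fit to the
    crown-area moments.  Derived basal area, volume and carbon use the given
    allometry.
    """
    rng = np.random.default_rng(config.seed)
    area_ha = config.stand_polygon.area_ha
    n = int(rng.poisson(config.target_density * area_ha))
    n = max(n, 2)
    xy = _place_trees(rng, config, n)

    a = (config.height_min - config.height_mean) / config.height_sd
    b = (config.height_max - config.height_mean) / config.height_sd
    heights = stats.truncnorm.rvs(
        a, b, loc=config.height_mean, scale=config.height_sd,
        size=n, random_state=rng,
    )

    # DBH linear in height: slope from the target correlation and SD ratio,
    # residual SD chosen so the marginal DBH SD matches the configured value
    r = config.dbh_height_corr
    slope = r * config.dbh_sd / config.height_sd
    resid_sd = config.dbh_sd * math.sqrt(max(1.0 - r**2, 0.0))
    intercept = config.dbh_mean - slope * config.height_mean
    dbh = intercept + slope * heights + rng.normal(0.0, resid_sd, size=n)
    dbh = np.clip(dbh, 5.0, None)  # physical floor

    # lognormal crown areas matched to the configured mean/SD by moments
    m, s = config.crown_area_mean, config.crown_area_sd
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    areas = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    crown_radius = np.sqrt(areas / math.pi)

    trees = pd.DataFrame(
        {
            "tree_id": np.arange(1, n + 1),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "height_m": heights,
            "dbh_cm": dbh,
            "species": config.species,
            "crown_radius_m": crown_radius,
        }
    )
    trees["basal_area_m2"] = basal_area(trees["dbh_cm"].to_numpy())
    trees["volume_m3"] = stem_volume(
        trees["dbh_cm"].to_numpy(), trees["height_m"].to_numpy(), allometry
    )
    trees["carbon_MgC"] = carbon_stock(trees["volume_m3"].to_numpy(), allometry)
    return trees


def terrain_height(
    x: np.ndarray, y: np.ndarray, config: SyntheticStandConfig
) -> np.ndarray:
    """Planar terrain ramp rising along +x at the configured slope."""
    return np.tan(math.radians(config.terrain_slope_deg)) * np.asarray(x)


def render_surfaces(
    trees: pd.DataFrame,
    config: SyntheticStandConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Raster, Raster]:
    """Rasterize the terrain (DTM) and canopy surface (DSM).

    Each tree adds a crown of profile ``z(r) = ground + H·(1 − (r/R)^a)``
    for r ≤ R; the DSM is the cellwise max of terrain and all crowns plus
    optional Gaussian surface noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cs = config.cell_size
    if len(trees) and cs > trees["crown_radius_m"].min():
        import warnings

        warnings.warn(
            "cell size exceeds the smallest crown radius; small crowns may "
            "not be resolved",
            stacklevel=2,
        )
    w = config.stand_width
    ncols = nrows = int(math.ceil(w / cs))
    origin_y = nrows * cs
    dtm_r = Raster(np.empty((nrows, ncols)), 0.0, origin_y, cs)
    xg, yg = dtm_r.center_grids()
    ground = terrain_height(xg, yg, config)
    dtm = Raster(ground, 0.0, origin_y, cs)

    surface = ground.copy()
    a = config.crown_shape_exponent
    for t in trees.itertuples():
        R = t.crown_radius_m
        if R <= 0:
            continue
        r0, c0 = dtm.cell_index(t.x - R, t.y + R)
        r1, c1 = dtm.cell_index(t.x + R, t.y - R)
        r0, r1 = max(r0, 0), min(r1 + 1, nrows)
        c0, c1 = max(c0, 0), min(c1 + 1, ncols)
        if r0 >= r1 or c0 >= c1:
            continue
        xs = xg[r0:r1, c0:c1]
        ys = yg[r0:r1, c0:c1]
        rr = np.hypot(xs - t.x, ys - t.y)
        gbase = terrain_height(np.array(t.x), np.array(t.y), config)
        crown = gbase + t.height_m * (1.0 - (np.minimum(rr, R) / R) ** a)
        crown[rr > R] = -np.inf
        np.maximum(surface[r0:r1, c0:c1], crown, out=surface[r0:r1, c0:c1])
    if config.surface_noise_sd > 0:
        surface = surface + rng.normal(0.0, config.surface_noise_sd, surface.shape)
    dsm = Raster(surface, 0.0, origin_y, cs)
    return dtm, dsm


def sample_point_cloud(
    dsm: Raster,
    config: SyntheticStandConfig,
    rng: np.random.Generator | None = None,
) -> PointCloud:
    """Scatter points uniformly over the DSM extent, bilinear z plus noise.

    Point count is ``round(point_density × area)``; deterministic given the
    rng state.
    """
    if config.point_density <= 0:
        raise ValueError("point_density must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    nrows, ncols = dsm.shape
    width = ncols * dsm.cell_size
    height = nrows * dsm.cell_size
    n = int(round(config.point_density * width * height))
    x = dsm.origin_x + rng.uniform(0.0, width, size=n)
    y = dsm.origin_y - rng.uniform(0.0, height, size=n)
    z = dsm.interpolate(x, y)
    if config.surface_noise_sd > 0:
        z = z + rng.normal(0.0, config.surface_noise_sd, size=n)
    return PointCloud(x, y, z)


def write_tree_list_csv(trees: pd.DataFrame, path) -> None:
    cols = ["tree_id", "x", "y", "height_m", "dbh_cm", "species", "crown_radius_m"]
    trees[cols].to_csv(path, index=False)


def read_tree_list_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
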