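"""End-to-end orchestration: simulate → grid → CHM → filter → detect →
match → crowns → metrics → models, with per-stage logging and file reports.

Every stage logs one line with its elapsed time and output row count, and
every intermediate artifact is written to the output directory so runs can be
inspected.  All randomness flows from the single config seed; re-running an
identical config reproduces the reports byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crowns as crowns_mod
from . import synthetic
from .evaluation import detection_report, match_treetops, stem_density
from .metrics import (
    AllometryParams,
    extract_heights,
    summarize_stand,
    tree_metrics_table,
)
from .models import fit_stand_models, near_distance
from .raster import (
    Raster,
    StandPolygon,
    clip_to_polygon,
    compute_chm,
    fill_voids,
    grid_points_to_dsm,
    read_ascii_grid,
    read_point_cloud_csv,
    read_stand_geojson,
    write_ascii_grid,
)
from .smoothing import FilterSpec, apply_filter
from .treetops import detect_local_maxima

log = logging.getLogger("chmstand")


@dataclass
class RunConfig:
    """Configuration for a pipeline run; mirrors the YAML schema."""

    output_dir: str = "chmstand_out"
    seed: int = 0
    cell_size: float = 0.5
    # inputs (either a synthetic block or file paths)
    synthetic: dict | None = None
    dsm_path: str | None = None
    dtm_path: str | None = None
    point_cloud_path: str | None = None
    field_csv: str | None = None
    stand_geojson: str | None = None
    manual_crowns_geojson: str | None = None
    # detection grid: list of dicts {filter, radius_or_sigma, window, search_radius,
    # fixed_window}
    filter_grid: list = field(default_factory=list)
    match_threshold: float | None = None  # None => equal to the search radius
    maxcrown: float = 0.4
    exclusion: float = 0.7
    min_height: float = 1.37
    allometry: dict = field(default_factory=dict)
    model_responses: list = field(default_factory=lambda: ["dbh_cm"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def allometry_params(self) -> AllometryParams:
        return AllometryParams(**self.allometry)

    def validate_detection(self) -> None:
        if not self.filter_grid:
            raise ValueError("filter_grid must list at least one setting")


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    holder = {"rows": None}
    yield holder
    dt = time.perf_counter() - t0
    log.info("stage=%s elapsed=%.3fs rows=%s", name, dt, holder["rows"])


def _filter_spec(entry: dict) -> FilterSpec | None:
    method = entry.get("filter")
    if method in (None, "none"):
        return None
    return FilterSpec(
        method=method,
        radius_or_sigma=entry.get("radius_or_sigma"),
        window=entry.get("window"),
        unit=entry.get("unit", "m"),
    )


def _detect_kwargs(entry: dict) -> dict:
    if entry.get("fixed_window") is not None:
        return {"fixed_window": int(entry["fixed_window"])}
    return {"search_radius": float(entry["search_radius"])}


def prepare_chm(config: RunConfig, out: Path) -> tuple[Raster, StandPolygon, pd.DataFrame]:
    """Build the CHM and field tree list from synthetic or file inputs."""
    params = config.allometry_params()
    if config.synthetic is not None:
        sconf = synthetic.SyntheticStandConfig(
            seed=config.seed, cell_size=config.cell_size, **config.synthetic
        )
        with _stage("simulate") as st:
            trees = synthetic.generate_tree_list(sconf, params)
            dtm, dsm = synthetic.render_surfaces(trees, sconf)
            st["rows"] = len(trees)
        synthetic.write_tree_list_csv(trees, out / "trees.csv")
        write_ascii_grid(dtm, out / "dtm.asc")
        write_ascii_grid(dsm, out / "dsm.asc")
        poly = sconf.stand_polygon
    else:
        if config.field_csv is None:
            raise ValueError("field_csv is required for file-based runs")
        trees = pd.read_csv(config.field_csv)
        poly = (
            read_stand_geojson(config.stand_geojson)
            if config.stand_geojson
            else None
        )
        if config.point_cloud_path is not None:
            with _stage("grid") as st:
                cloud = read_point_cloud_csv(config.point_cloud_path)
                dsm = grid_points_to_dsm(cloud, config.cell_size)
                dsm = fill_voids(dsm)
                st["rows"] = len(cloud)
        elif config.dsm_path is not None:
            dsm = read_ascii_grid(config.dsm_path)
        else:
            raise ValueError("need a point cloud or a DSM input")
        if config.dtm_path is None:
            raise ValueError("a DTM input is required to compute the CHM")
        dtm = read_ascii_grid(config.dtm_path)
        if poly is None:
            raise ValueError("stand_geojson is required for file-based runs")

    with _stage("chm") as st:
        chm = compute_chm(dsm, dtm)
        chm = clip_to_polygon(chm, poly)
        st["rows"] = int(chm.valid_mask.sum())
    write_ascii_grid(chm, out / "chm.asc")
    return chm, poly, trees


def run_detection_experiment(config: RunConfig) -> pd.DataFrame:
    """Detection over the configured filter grid, scored against field trees.

    Writes the per-setting report CSV (treetop count, density, TP/FP/FN,
    precision, recall, F-score) plus per-setting treetop GeoJSONs.
    """
    config.validate_detection()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chm, poly, trees = prepare_chm(config, out)
    field_xy = trees[["x", "y"]].to_numpy()
    field_ids = trees["tree_id"].to_numpy()

    rows = []
    for entry in config.filter_grid:
        fspec = _filter_spec(entry)
        detect_kw = _detect_kwargs(entry)
        label = fspec.label() if fspec else "none"
        with _stage(f"detect[{label}]") as st:
            smoothed = apply_filter(chm, fspec) if fspec else chm
            tops = detect_local_maxima(
                smoothed, min_height=config.min_height, **detect_kw
            )
            st["rows"] = len(tops)
        tops.to_geojson(out / f"treetops_{label}_{list(detect_kw.values())[0]}.geojson")
        threshold = config.match_threshold
        if threshold is None:
            threshold = detect_kw.get("search_radius") or (
                detect_kw["fixed_window"] * chm.cell_size / 2.0
            )
        result = match_treetops(
            np.column_stack([tops.x, tops.y]),
            tops.treetop_id,
            field_xy,
            field_ids,
            threshold=threshold,
        )
        rows.append(
            {
                "filter": label,
                "search_radius_m": detect_kw.get("search_radius"),
                "treetop_count": len(tops),
                "density_stems_ha": round(stem_density(len(tops), poly), 2),
                "result": result,
            }
        )
    report = detection_report(rows)
    report.to_csv(out / "detection_report.csv", index=False)
    return report


def run_full_analysis(config: RunConfig) -> tuple[dict, dict]:
    """Full workflow: detection, heights, crowns, stand summary, MLR models.

    Returns (stand summary dict, model report dict); writes tree metrics CSV,
    stand summary JSON, crown GeoJSON, and per-response model reports.
    """
    config.validate_detection()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.allometry_params()
    chm, poly, trees = prepare_chm(config, out)

    entry = config.filter_grid[0]
    fspec = _filter_spec(entry)
    detect_kw = _detect_kwargs(entry)
    with _stage("detect") as st:
        smoothed = apply_filter(chm, fspec) if fspec else chm
        tops = detect_local_maxima(smoothed, min_height=config.min_height, **detect_kw)
        st["rows"] = len(tops)

    with _stage("heights") as st:
        uav_heights = extract_heights(smoothed, tops)
        st["rows"] = len(uav_heights)

    with _stage("crowns") as st:
        crowns = crowns_mod.delineate_crowns(
            chm, tops, maxcrown=config.maxcrown, exclusion=config.exclusion
        )
        st["rows"] = len(crowns)
    crowns_mod.write_crowns_geojson(crowns, chm, out / "crowns.geojson")

    with _stage("metrics") as st:
        tree_table = tree_metrics_table(trees, params)
        summary = summarize_stand(tree_table, poly, params)
        st["rows"] = summary.n_trees
    tree_table.to_csv(out / "tree_metrics.csv", index=False)
    with open(out / "stand_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)

    # predictor table: match detected trees back to field trees one-to-one
    threshold = config.match_threshold or detect_kw.get("search_radius", 2.0)
    result = match_treetops(
        np.column_stack([tops.x, tops.y]),
        tops.treetop_id,
        trees[["x", "y"]].to_numpy(),
        trees["tree_id"].to_numpy(),
        threshold=threshold,
    )
    crown_area = {c.treetop_id: c.area for c in crowns}
    crown_peri = {c.treetop_id: c.perimeter for c in crowns}
    height_by_top = dict(
        zip(uav_heights["treetop_id"], uav_heights["height_m"])
    )
    nd = near_distance(tops.x, tops.y)
    nd_by_top = dict(zip(tops.treetop_id, nd))

    manual_area = None
    used_manual = config.manual_crowns_geojson is not None
    if used_manual:
        manual_area = crowns_mod.read_manual_crowns_geojson(
            config.manual_crowns_geojson
        )
    else:
        log.info("no manual crowns supplied; auto crown area substitutes")

    rows = []
    tree_by_id = tree_table.set_index("tree_id")
    for field_id, top_id, _dist in result.matched_pairs:
        rec = {
            "tree_id": field_id,
            "uav_height": height_by_top[top_id],
            "auto_crown_area": crown_area[top_id],
            "crown_perimeter": crown_peri[top_id],
            "near_distance": nd_by_top[top_id],
            "manual_crown_area": (
                manual_area.get(field_id, np.nan) if used_manual
                else crown_area[top_id]
            ),
        }
        for resp in config.model_responses:
            if resp not in tree_by_id.columns:
                raise ValueError(f"response column {resp!r} missing from tree list")
            rec[resp] = tree_by_id.loc[field_id, resp]
        rows.append(rec)
    table = pd.DataFrame(rows).dropna()
    table.to_csv(out / "predictor_table.csv", index=False)

    predictor_cols = [
        "uav_height", "manual_crown_area", "auto_crown_area",
        "crown_perimeter", "near_distance",
    ]
    if not used_manual:
        # identical to auto_crown_area; keep one copy in the pool
        predictor_cols.remove("manual_crown_area")
    with _stage("models") as st:
        fits = fit_stand_models(table, config.model_responses, predictor_cols)
        st["rows"] = len(table)
    model_report = {
        resp: {**fit.report(), "manual_crown_source": "manual" if used_manual
               else "auto (fallback)"}
        for resp, fit in fits.items()
    }
    with open(out / "model_report.json", "w") as fh:
        json.dump(model_report, fh, indent=2)
    return summary.to_dict(), model_report
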