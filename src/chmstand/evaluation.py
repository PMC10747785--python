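"""Detection accuracy: treetop-to-field matching, precision/recall/F-score,
and stem density.

Matching is one-to-one optimal assignment: among all pairings of field trees
to detected treetops with pair distance at most the threshold, the matching
with maximum cardinality and, among those, minimum total distance is chosen
(Hungarian algorithm on a large-penalty cost matrix).  Unlike nearest-first
greedy acceptance, this never sacrifices a feasible match to a locally closer
pair.  Unmatched treetops are false positives; unmatched field trees are
false negatives.  True negatives have no countable unit on a continuous
surface and are reported as zero; they do not enter any of the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import StandPolygon


@dataclass
class DetectionResult:
    """Matched (field_id, treetop_id, distance) pairs plus confusion counts."""

    matched_pairs: list[tuple[int, int, float]]
    tp: int
    fp: int
    fn: int
    tn: int = 0
    threshold: float = float("nan")


def match_treetops(
    detected_xy: np.ndarray,
    detected_ids: np.ndarray,
    field_xy: np.ndarray,
    field_ids: np.ndarray,
    threshold: float,
) -> DetectionResult:
    """Optimal one-to-one matching of detected treetops to field trees.

    Parameters are coordinate arrays of shape (n, 2) with parallel id arrays;
    ``threshold`` is the maximum pairing distance in meters (conventionally
    the detection search radius).
    """
    if threshold <= 0:
        raise ValueError("matching threshold must be positive")
    detected_xy = np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    field_xy = np.asarray(field_xy, dtype=float).reshape(-1, 2)

    matched: list[tuple[int, int, float]] = []
    if len(detected_xy) and len(field_xy):
        from scipy.optimize import linear_sum_assignment
        from scipy.spatial.distance import cdist

        dmat = cdist(field_xy, detected_xy)
        # infeasible pairs get a penalty larger than any feasible total cost,
        # so the solver first maximizes cardinality, then minimizes distance
        penalty = threshold * (dmat.size + 1.0)
        cost = np.where(dmat <= threshold, dmat, penalty)
        fi, di = linear_sum_assignment(cost)
        for f, d in zip(fi, di):
            if dmat[f, d] <= threshold:
                matched.append(
                    (int(field_ids[f]), int(detected_ids[d]), float(dmat[f, d]))
                )

    tp = len(matched)
    return DetectionResult(
        matched_pairs=matched,
        tp=tp,
        fp=len(detected_xy) - tp,
        fn=len(field_xy) - tp,
        tn=0,
        threshold=threshold,
    )


def detection_scores(result: DetectionResult) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F-score (harmonic mean).

    Full precision is returned; round only for display.  With no detections
    and no field trees the scores are undefined and returned as NaN.
    """
    tp, fp, fn = result.tp, result.fp, result.fn
    if tp + fp + fn == 0:
        return (math.nan, math.nan, math.nan)
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    f_score = 2 * tp / (2 * tp + fp + fn) if tp > 0 else 0.0
    if tp == 0 and (fp == 0 or fn == 0):
        # one of precision/recall is 0/0
        f_score = math.nan if (fp == 0 and fn == 0) else 0.0
    return (precision, recall, f_score)


def stem_density(count: int, poly: StandPolygon) -> float:
    """Stems per hectare from a tree count and the stand polygon."""
    if poly.area_ha <= 0:
        raise ValueError("stand polygon area must be positive")
    return count / poly.area_ha


def detection_report(
    rows: list[dict],
) -> pd.DataFrame:
    """Assemble the per-setting detection report table.

    Each input dict carries: filter label, radius/window, treetop count,
    density, and a :class:`DetectionResult`.  Scores are computed here and
    displayed at 2 decimal places alongside the full-precision values.
    """
    out = []
    for r in rows:
        res: DetectionResult = r["result"]
        precision, recall, f_score = detection_scores(res)
        out.append(
            {
                "filter": r["filter"],
                "search_radius_m": r.get("search_radius_m"),
                "treetop_count": r["treetop_count"],
                "density_stems_ha": r["density_stems_ha"],
                "tp": res.tp,
                "fp": res.fp,
                "fn": res.fn,
                "precision": round(precision, 2),
                "recall": round(recall, 2),
                "f_score": round(f_score, 2),
            }
        )
    return pd.DataFrame(out)
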