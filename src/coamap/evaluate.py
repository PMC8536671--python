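"""Evaluation of detection output against generating truth.

The expected detection set for a synthetic field is the set of generated
discs that (i) reach the minimum equivalent diameter and (ii) do not touch
the left or bottom image border in the raster — computed here with the same
pixel-centre-in-disc predicate the rasteriser uses, so the oracle is exact.
Detected objects are matched to truth greedily by centroid distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import Calibration
from .detection import CoAObject


def disc_border_touches(
    cx_um: float, cy_um: float, diameter_um: float, calibration: Calibration
) -> dict:
    """Which image borders a rasterised disc touches (exact predicate).

    Pixel (i, j) lies in the disc iff its centre ((j+0.5)ps, (i+0.5)ps) is
    within the radius of the disc centre.
    """
    ps = calibration.pixel_size_um
    w, h = calibration.fov_width_px, calibration.fov_height_px
    r2 = (diameter_um / 2) ** 2

    def nearest_center(c_um: float, n: int) -> float:
        idx = min(max(round(c_um / ps - 0.5), 0), n - 1)
        return (idx + 0.5) * ps

    x_near = nearest_center(cx_um, w)
    y_near = nearest_center(cy_um, h)
    return {
        "left": (0.5 * ps - cx_um) ** 2 + (y_near - cy_um) ** 2 <= r2,
        "right": ((w - 0.5) * ps - cx_um) ** 2 + (y_near - cy_um) ** 2 <= r2,
        "top": (x_near - cx_um) ** 2 + (0.5 * ps - cy_um) ** 2 <= r2,
        "bottom": (x_near - cx_um) ** 2 + ((h - 0.5) * ps - cy_um) ** 2 <= r2,
    }


def expected_detections(
    truth_objects: pd.DataFrame, calibration: Calibration, min_diameter_um: float = 3.0
) -> pd.DataFrame:
    """Truth rows that the filter rules should retain, with an ``interior``
    flag for discs clear of every border (usable for size-error oracles)."""
    rows = []
    for _, t in truth_objects.iterrows():
        touches = disc_border_touches(
            t["centroid_x_um"], t["centroid_y_um"], t["true_diameter_um"], calibration
        )
        if t["true_diameter_um"] < min_diameter_um:
            continue
        if touches["left"] or touches["bottom"]:
            continue
        rows.append({**t.to_dict(), "interior": not (touches["right"] or touches["top"])})
    return pd.DataFrame(rows, columns=list(truth_objects.columns) + ["interior"])


@dataclass
class MatchResult:
    n_truth: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float
    diameter_mae_um: float  # over matched pairs with fully interior truth discs
    centroid_mae_um: float


def match_detections(
    detected: list,
    truth_objects: pd.DataFrame,
    calibration: Calibration,
    min_diameter_um: float = 3.0,
    max_dist_um: float = 3.0,
) -> MatchResult:
    """Greedy nearest-centroid matching of detections to expected truth."""
    expected = expected_detections(truth_objects, calibration, min_diameter_um)
    n_t, n_d = len(expected), len(detected)
    if n_t == 0 or n_d == 0:
        return MatchResult(n_t, n_d, 0, math.nan if n_t == 0 else 0.0,
                           math.nan if n_d == 0 else 0.0, math.nan, math.nan)
    tx = expected["centroid_x_um"].to_numpy()
    ty = expected["centroid_y_um"].to_numpy()
    dx = np.array([o.centroid_x_um for o in detected])
    dy = np.array([o.centroid_y_um for o in detected])
    dist = np.hypot(tx[:, None] - dx[None, :], ty[:, None] - dy[None, :])

    pairs = []
    order = np.argsort(dist, axis=None)
    used_t: set = set()
    used_d: set = set()
    for flat in order:
        i, j = np.unravel_index(flat, dist.shape)
        if dist[i, j] > max_dist_um:
            break
        if i in used_t or j in used_d:
            continue
        used_t.add(int(i))
        used_d.add(int(j))
        pairs.append((int(i), int(j), float(dist[i, j])))

    diam_errors = []
    cent_errors = []
    for i, j, d in pairs:
        cent_errors.append(d)
        if bool(expected.iloc[i]["interior"]):
            diam_errors.append(
                abs(detected[j].equivalent_diameter_um - float(expected.iloc[i]["true_diameter_um"]))
            )
    n_m = len(pairs)
    return MatchResult(
        n_truth=n_t,
        n_detected=n_d,
        n_matched=n_m,
        recall=n_m / n_t,
        precision=n_m / n_d,
        diameter_mae_um=float(np.mean(diam_errors)) if diam_errors else math.nan,
        centroid_mae_um=float(np.mean(cent_errors)) if cent_errors else math.nan,
    )


def pool_matches(results: list) -> MatchResult:
    """Pool per-field match results into overall recall/precision/MAE."""
    n_t = sum(r.n_truth for r in results)
    n_d = sum(r.n_detected for r in results)
    n_m = sum(r.n_matched for r in results)
    maes = [(r.diameter_mae_um, r.n_matched) for r in results if math.isfinite(r.diameter_mae_um)]
    mae = (
        sum(m * w for m, w in maes) / sum(w for _, w in maes) if maes else math.nan
    )
    return MatchResult(
        n_truth=n_t,
        n_detected=n_d,
        n_matched=n_m,
        recall=n_m / n_t if n_t else math.nan,
        precision=n_m / n_d if n_d else math.nan,
        diameter_mae_um=mae,
        centroid_mae_um=math.nan,
    )
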