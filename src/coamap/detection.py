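"""CoA detection: binarise, label, measure, filter.

The measurement rules follow the acquisition protocol the pipeline targets:
objects smaller than 3 um equivalent diameter are discarded, and objects
intersecting the left or bottom image border are excluded (an unbiased
counting frame: right/top-touching objects are retained, so tiled fields
count each object exactly once). Areas are exact pixel counts times the
pixel area; the equivalent diameter is that of the circle with the same
area, 2*sqrt(area/pi).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .calibration import Calibration
from .image import Micrograph


@dataclass
class CoAObject:
    """One detected inclusion with calibrated measurements.

    Centroids are pixel-centre means in um (origin top-left, x rightward,
    y downward). ``depth_um``/``zone`` are filled by zone assignment.
    """

    object_id: int
    centroid_x_um: float
    centroid_y_um: float
    area_um2: float
    equivalent_diameter_um: float
    touches_left: bool
    touches_bottom: bool
    touches_right: bool
    touches_top: bool
    pixel_count: int
    fov_id: str = ""
    depth_um: float | None = None
    zone: str | None = None


def binarize(image: Micrograph, method: str = "otsu", level: float | None = None) -> np.ndarray:
    """Threshold a micrograph into a candidate-foreground mask.

    ``method="otsu"`` picks the threshold automatically (a constant image
    yields an empty mask); ``method="fixed"`` uses ``level``, which must lie
    within the representable intensity range of the image dtype. A fixed
    level at or below the image minimum marks everything foreground and is
    reported with a warning.
    """
    pixels = image.pixels
    if method == "otsu":
        if pixels.min() == pixels.max():
            return np.zeros(pixels.shape, dtype=bool)
        thr = threshold_otsu(pixels)
        return pixels > thr
    if method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
        if np.issubdtype(pixels.dtype, np.integer):
            info = np.iinfo(pixels.dtype)
            if not (info.min <= level <= info.max):
                raise ValueError(
                    f"fixed level {level} outside representable range "
                    f"[{info.min}, {info.max}] of dtype {pixels.dtype}"
                )
        mask = pixels > level
        if mask.all():
            warnings.warn(
                f"fixed threshold {level} below all image intensities: "
                "full-foreground mask",
                stacklevel=2,
            )
        return mask
    raise ValueError(f"unknown binarization method: {method!r}")


def extract_objects(mask: np.ndarray, calibration: Calibration, fov_id: str = "") -> list:
    """8-connected components of a mask as measured objects (pre-filter).

    Object order is deterministic: row-major by first pixel (the labelling
    scan order). Centroids are converted to um at pixel centres; border-touch
    flags come from the component bounding box.
    """
    h, w = mask.shape
    if (w, h) != (calibration.fov_width_px, calibration.fov_height_px):
        raise ValueError("mask dimensions do not match calibration")
    labels = measure.label(mask, connectivity=2)
    ps = calibration.pixel_size_um
    objects = []
    for prop in measure.regionprops(labels):
        npx = int(prop.area)
        area_um2 = npx * calibration.pixel_area_um2
        cy, cx = prop.centroid  # (row, col) in pixel indices
        minr, minc, maxr, maxc = prop.bbox
        objects.append(
            CoAObject(
                object_id=int(prop.label) - 1,
                centroid_x_um=(cx + 0.5) * ps,
                centroid_y_um=(cy + 0.5) * ps,
                area_um2=area_um2,
                equivalent_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
                touches_left=minc == 0,
                touches_bottom=maxr == h,
                touches_right=maxc == w,
                touches_top=minr == 0,
                pixel_count=npx,
                fov_id=fov_id,
            )
        )
    return objects


def filter_objects(objects: list, min_diameter_um: float = 3.0) -> list:
    """Apply the minimum-size and counting-frame rules.

    Retains objects with equivalent diameter >= ``min_diameter_um`` that do
    not touch the left or bottom border; right/top-touching objects are
    retained. Input order is preserved.
    """
    return [
        o
        for o in objects
        if o.equivalent_diameter_um >= min_diameter_um
        and not o.touches_left
        and not o.touches_bottom
    ]


def detect(
    image: Micrograph,
    method: str = "otsu",
    level: float | None = None,
    min_diameter_um: float = 3.0,
) -> list:
    """Full detection pipeline: binarize -> extract -> filter."""
    mask = binarize(image, method=method, level=level)
    objects = extract_objects(mask, image.calibration, fov_id=image.fov_id)
    return filter_objects(objects, min_diameter_um=min_diameter_um)


def objects_to_frame(objects: list) -> pd.DataFrame:
    """Tabulate measured objects (one row per retained object)."""
    cols = [
        "fov_id",
        "object_id",
        "centroid_x_um",
        "centroid_y_um",
        "area_um2",
        "equivalent_diameter_um",
        "pixel_count",
        "touches_left",
        "touches_bottom",
        "touches_right",
        "touches_top",
        "depth_um",
        "zone",
    ]
    if not objects:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{c: getattr(o, c) for c in cols} for o in objects])


def save_qc_overlay(image: Micrograph, mask: np.ndarray, path) -> None:
    """Write a quick-look PNG with the detection mask outlined in red."""
    import imageio.v3 as iio
    from skimage.segmentation import find_boundaries

    lo, hi = float(image.pixels.min()), float(image.pixels.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    gray = ((image.pixels - lo) * scale).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    edges = find_boundaries(mask, mode="outer")
    rgb[edges] = (255, 0, 0)
    iio.imwrite(path, rgb)
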