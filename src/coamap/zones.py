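"""Per-FOV parameters and HD/LD zone analytics.

Five parameters summarise each field of view: CoA count, area fraction (%),
and the mean, minimum and maximum equivalent diameters (the minimum/maximum
being the diameter of the single smallest/largest object in the field).
Empty fields record 0 for count and area and missing (NaN) diameters, which
are excluded from any diameter statistics downstream.

Pial-surface fields are split into a high-density (HD) band extending from
the pial border to a fixed per-region depth (100 um at the fimbria, 70 um at
the prosubiculum, 40 um elsewhere) and a low-density (LD) remainder. Zone
membership is by object centroid, with the boundary depth inclusive to HD.
The HD-band thickness of a traced polygon is estimated as enclosed area
divided by the length of its centre line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from .calibration import Calibration
from .detection import CoAObject
from .regions import Region, hd_depth_for, is_pial

logger = logging.getLogger(__name__)

MISSING = float("nan")


@dataclass
class FOVSummary:
    """The five per-FOV parameters plus the region label."""

    fov_id: str
    region: Region
    count: int
    area_fraction_pct: float
    mean_diameter_um: float
    min_diameter_um: float
    max_diameter_um: float


def summarize_fov(
    objects: list,
    calibration: Calibration,
    region: Region | str,
    fov_id: str = "",
) -> FOVSummary:
    """Compute the five parameters for one field of view."""
    region = Region(region)
    if not objects:
        return FOVSummary(fov_id, region, 0, 0.0, MISSING, MISSING, MISSING)
    diameters = np.array([o.equivalent_diameter_um for o in objects])
    total_area = float(sum(o.area_um2 for o in objects))
    return FOVSummary(
        fov_id=fov_id,
        region=region,
        count=len(objects),
        area_fraction_pct=100.0 * total_area / calibration.fov_area_um2,
        mean_diameter_um=float(diameters.mean()),
        min_diameter_um=float(diameters.min()),
        max_diameter_um=float(diameters.max()),
    )


def summaries_to_frame(summaries: list, section_ids: list | None = None) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(summaries):
        row = {
            "fov_id": s.fov_id,
            "region": s.region.value,
            "count": s.count,
            "area_fraction_pct": s.area_fraction_pct,
            "mean_diameter_um": s.mean_diameter_um,
            "min_diameter_um": s.min_diameter_um,
            "max_diameter_um": s.max_diameter_um,
        }
        if section_ids is not None:
            row["section_id"] = section_ids[i]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# zone partition


@dataclass
class ZonePartition:
    """HD/LD split of one pial-surface field.

    ``pial_border`` is a polyline in um coordinates; the HD polygon is the
    band within ``hd_depth_um`` of the border (clipped to the field), the LD
    polygon the remainder.
    """

    region: Region
    hd_depth_um: float
    pial_border: LineString
    hd_polygon: Polygon
    ld_polygon: Polygon

    @property
    def hd_area_mm2(self) -> float:
        return self.hd_polygon.area / 1e6

    @property
    def ld_area_mm2(self) -> float:
        return self.ld_polygon.area / 1e6

    @classmethod
    def straight_top_edge(
        cls,
        region: Region | str,
        calibration: Calibration,
        hd_depth_um: float | None = None,
    ) -> "ZonePartition":
        """Partition with the pial border along the top image edge."""
        region = Region(region)
        if hd_depth_um is None:
            hd_depth_um = hd_depth_for(region)
            if hd_depth_um is None:
                raise ValueError(f"{region.value} is not a pial-surface region")
        w, h = calibration.fov_width_um, calibration.fov_height_um
        if not 0 < hd_depth_um < h:
            raise ValueError("hd_depth_um must lie strictly inside the field height")
        border = LineString([(0.0, 0.0), (w, 0.0)])
        return cls(
            region=region,
            hd_depth_um=float(hd_depth_um),
            pial_border=border,
            hd_polygon=box(0.0, 0.0, w, hd_depth_um),
            ld_polygon=box(0.0, hd_depth_um, w, h),
        )

    @classmethod
    def from_border(
        cls,
        region: Region | str,
        calibration: Calibration,
        border: LineString | list,
        hd_depth_um: float | None = None,
    ) -> "ZonePartition":
        """Partition from a traced (possibly curved) pial-border polyline."""
        region = Region(region)
        if hd_depth_um is None:
            hd_depth_um = hd_depth_for(region)
            if hd_depth_um is None:
                raise ValueError(f"{region.value} is not a pial-surface region")
        if not isinstance(border, LineString):
            border = LineString(border)
        fov = box(0.0, 0.0, calibration.fov_width_um, calibration.fov_height_um)
        hd = border.buffer(hd_depth_um).intersection(fov)
        ld = fov.difference(hd)
        return cls(
            region=region,
            hd_depth_um=float(hd_depth_um),
            pial_border=border,
            hd_polygon=hd,
            ld_polygon=ld,
        )


def estimate_hd_thickness(hd_polygon, centre_line) -> float:
    """HD-zone depth as enclosed area divided by centre-line length (um)."""
    if not isinstance(hd_polygon, Polygon):
        hd_polygon = Polygon(hd_polygon)
    if not isinstance(centre_line, LineString):
        centre_line = LineString(centre_line)
    if centre_line.length <= 0:
        raise ValueError("centre line must have positive length")
    return hd_polygon.area / centre_line.length


def assign_zones(objects: list, partition: ZonePartition | None) -> list:
    """Label each object HD or LD by centroid depth below the pial border.

    Boundary-depth centroids go to HD. A ``None`` partition (neuropil field,
    no pial border) labels everything LD. Objects are modified in place and
    returned.
    """
    for o in objects:
        if partition is None:
            o.depth_um = None
            o.zone = "LD"
            continue
        p = Point(o.centroid_x_um, o.centroid_y_um)
        depth = partition.pial_border.distance(p)
        o.depth_um = depth
        # boundary inclusive to HD; tolerance absorbs geometric rounding
        at_boundary = math.isclose(depth, partition.hd_depth_um, rel_tol=1e-9, abs_tol=1e-9)
        o.zone = "HD" if (depth <= partition.hd_depth_um or at_boundary) else "LD"
        if not (partition.hd_polygon.covers(p) or partition.ld_polygon.covers(p)):
            # numerical sliver outside both polygons: keep the depth rule
            logger.warning(
                "centroid (%.2f, %.2f) outside both zone polygons; assigned %s by depth",
                o.centroid_x_um, o.centroid_y_um, o.zone,
            )
    return objects


@dataclass
class ZoneSummary:
    """Packing density and size statistics for one zone of one field."""

    region: Region
    zone: str
    count: int
    packing_density_per_mm2: float
    area_fraction_pct: float
    mean_diameter_um: float
    max_diameter_um: float


def summarize_zone(objects: list, partition: ZonePartition, zone: str) -> ZoneSummary:
    """Summarise the objects of one zone against the zone's own area."""
    if zone not in ("HD", "LD"):
        raise ValueError("zone must be 'HD' or 'LD'")
    area_mm2 = partition.hd_area_mm2 if zone == "HD" else partition.ld_area_mm2
    if area_mm2 <= 0:
        raise ValueError(f"{zone} zone has non-positive area")
    members = [o for o in objects if o.zone == zone]
    if not members:
        return ZoneSummary(partition.region, zone, 0, 0.0, 0.0, MISSING, MISSING)
    diameters = np.array([o.equivalent_diameter_um for o in members])
    total_area_um2 = float(sum(o.area_um2 for o in members))
    return ZoneSummary(
        region=partition.region,
        zone=zone,
        count=len(members),
        packing_density_per_mm2=len(members) / area_mm2,
        area_fraction_pct=100.0 * total_area_um2 / (area_mm2 * 1e6),
        mean_diameter_um=float(diameters.mean()),
        max_diameter_um=float(diameters.max()),
    )


def summarize_zones(objects: list, partition: ZonePartition) -> tuple:
    """(HD, LD) zone summaries for one field; assigns zones if needed."""
    if any(o.zone is None for o in objects):
        assign_zones(objects, partition)
    return (
        summarize_zone(objects, partition, "HD"),
        summarize_zone(objects, partition, "LD"),
    )


def zone_summaries_to_frame(
    summaries: list, fov_ids: list, section_ids: list | None = None
) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(summaries):
        row = {
            "fov_id": fov_ids[i],
            "region": s.region.value,
            "zone": s.zone,
            "count": s.count,
            "packing_density_per_mm2": s.packing_density_per_mm2,
            "area_fraction_pct": s.area_fraction_pct,
            "mean_diameter_um": s.mean_diameter_um,
            "max_diameter_um": s.max_diameter_um,
        }
        if section_ids is not None:
            row["section_id"] = section_ids[i]
        rows.append(row)
    return pd.DataFrame(rows)


def hd_ld_fold_change(hd_mean: float, ld_mean: float) -> float:
    """HD/LD ratio of per-region means; missing (NaN) when the LD mean is 0."""
    if ld_mean is None or not np.isfinite(ld_mean) or ld_mean == 0:
        logger.info("LD mean is zero or missing; HD/LD fold change undefined")
        return MISSING
    return hd_mean / ld_mean
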