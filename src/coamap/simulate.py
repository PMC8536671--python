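"""Synthetic micrograph generator with exact ground truth.

Emulates the statistical structure the analysis pipeline assumes, so every
downstream stage can be validated against known truth:

* corpora amylacea (CoA) are bright discs on a dim, noisy autofluorescence
  background;
* in pial-surface fields they concentrate in a subpial high-density (HD)
  band just beneath the pial border (rendered as the top image edge), with a
  lower uniform intensity in the deeper low-density (LD) remainder;
* per-field counts are Poisson; disc positions are uniform within their zone
  subject to a hard-core minimum separation (placed sequentially with
  rejection, so the count distribution is preserved);
* disc diameters follow a truncated lognormal (median 9 um by default,
  bounded to [3, 30] um);
* whole sections carry a stage 0-4 burden: density peaks at the fimbria pial
  surface and decays monotonically along the pial border to both sides, with
  deep-white-matter involvement at stages 3-4;
* cohorts add subject covariates (age, BMI, sex) with an optional age effect
  on the diameter location parameter and a stage assignment independent of
  age.

Everything is driven by a single :class:`numpy.random.Generator`, so a fixed
seed reproduces images and tables bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import DEFAULT_CALIBRATION, Calibration
from .image import Micrograph
from .regions import (
    ALL_REGIONS,
    HD_DEPTH_UM,
    PIAL_REGIONS,
    Region,
    hd_depth_for,
    is_pial,
)


class SimulationError(RuntimeError):
    """Raised when a field cannot be realised (e.g. hard-core packing fails)."""


@dataclass
class SimConfig:
    """Parameters of the synthetic generator.

    Intensities are expected CoA per mm^2 of HD zone; the LD zone receives
    ``ld_ratio`` times that intensity. Neuropil fields (no pial border) are
    uniform at the LD intensity. Diameters are lognormal on the log-um scale,
    truncated to ``diameter_bounds_um``.
    """

    seed: int = 0
    stage: int = 3
    hd_depth_um: dict = field(default_factory=lambda: dict(HD_DEPTH_UM))
    hd_intensity: float = 300.0  # CoA per mm^2 in the HD zone
    ld_ratio: float = 0.1  # LD/HD intensity ratio
    diameter_log_mu: float = math.log(9.0)  # log-um location (median 9 um)
    diameter_log_sigma: float = 0.3  # log-um scale
    diameter_bounds_um: tuple = (3.0, 30.0)
    background_level: float = 500.0
    background_noise_sd: float = 50.0
    blob_peak_level: float = 5000.0
    min_separation_um: float = 12.0  # hard-core centre-to-centre distance
    max_placement_attempts: int = 2000
    fovs_per_region: int = 3
    subjects: int = 30
    age_range: tuple = (42.0, 89.0)
    bmi_range: tuple = (20.0, 42.0)
    age_diameter_slope: float = 0.05  # um of median diameter per year of age

    def validate(self) -> None:
        lo, hi = self.diameter_bounds_um
        if not (0 < lo < hi):
            raise ValueError("diameter_bounds_um must satisfy 0 < min < max")
        if not (0 <= self.ld_ratio <= 1):
            raise ValueError("ld_ratio must lie in [0, 1]")
        if self.hd_intensity < 0:
            raise ValueError("hd_intensity must be non-negative")
        if self.stage not in (0, 1, 2, 3, 4):
            raise ValueError("stage must be an integer in 0..4")
        # detectability contract: discs must stand clear of the background
        if self.blob_peak_level <= self.background_level + 5 * self.background_noise_sd:
            raise ValueError(
                "blob_peak_level must exceed background_level + 5*background_noise_sd"
            )


@dataclass
class GroundTruth:
    """Exact generating truth for a set of fields.

    ``objects``: one row per disc (fov_id, section_id, region, object_id,
    centroid_x_um, centroid_y_um, true_diameter_um, zone).
    ``fovs``: one row per field (fov_id, section_id, region, true_count,
    true_area_fraction_pct).
    ``sections``: one row per section (section_id, true_stage, deep_wm_lv,
    deep_wm_phg_fusiform, plus covariates when generated by a cohort).
    """

    objects: pd.DataFrame
    fovs: pd.DataFrame
    sections: pd.DataFrame

    @staticmethod
    def empty() -> "GroundTruth":
        return GroundTruth(
            objects=pd.DataFrame(
                columns=[
                    "fov_id",
                    "section_id",
                    "region",
                    "object_id",
                    "centroid_x_um",
                    "centroid_y_um",
                    "true_diameter_um",
                    "zone",
                ]
            ),
            fovs=pd.DataFrame(
                columns=["fov_id", "section_id", "region", "true_count", "true_area_fraction_pct"]
            ),
            sections=pd.DataFrame(
                columns=["section_id", "true_stage", "deep_wm_lv", "deep_wm_phg_fusiform"]
            ),
        )

    @staticmethod
    def concat(parts: Iterable["GroundTruth"]) -> "GroundTruth":
        parts = list(parts)
        if not parts:
            return GroundTruth.empty()
        return GroundTruth(
            objects=pd.concat([p.objects for p in parts], ignore_index=True),
            fovs=pd.concat([p.fovs for p in parts], ignore_index=True),
            sections=pd.concat([p.sections for p in parts], ignore_index=True),
        )


# ---------------------------------------------------------------------------
# low-level sampling helpers


def sample_truncated_lognormal(
    rng: np.random.Generator,
    n: int,
    log_mu: float,
    log_sigma: float,
    bounds: tuple,
) -> np.ndarray:
    """Rejection-sample lognormal variates truncated to ``bounds``."""
    lo, hi = bounds
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        draw = np.exp(rng.normal(log_mu, log_sigma, size=max(n - filled, 16)))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _place_points(
    rng: np.random.Generator,
    n: int,
    x_range: tuple,
    y_range: tuple,
    existing: list,
    min_sep: float,
    max_attempts: int,
    context: str,
) -> list:
    """Sequentially place ``n`` uniform points at hard-core distance min_sep.

    Appends to and returns ``existing`` (list of (x, y)). Raises
    :class:`SimulationError` if a point cannot be placed within
    ``max_attempts`` rejections.
    """
    placed = []
    pts = np.array(existing, dtype=float).reshape(-1, 2)
    min_sep2 = min_sep**2
    for _ in range(n):
        for _attempt in range(max_attempts):
            x = rng.uniform(*x_range)
            y = rng.uniform(*y_range)
            if min_sep <= 0 or len(pts) == 0:
                ok = True
            else:
                d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
                ok = bool(d2.min() >= min_sep2)
            if ok:
                pts = np.vstack([pts, [x, y]])
                placed.append((x, y))
                break
        else:
            raise SimulationError(
                f"hard-core placement failed after {max_attempts} attempts ({context}); "
                "the requested intensity is too high for min_separation_um"
            )
    existing.extend(placed)
    return placed


def _rasterize_discs(
    shape: tuple,
    centers_px: np.ndarray,
    radii_px: np.ndarray,
    wrap: bool = False,
) -> np.ndarray:
    """Boolean raster of discs; pixel in disc iff its centre lies within the
    radius of the disc centre. ``wrap`` folds discs toroidally at the edges."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for (cx, cy), r in zip(centers_px, radii_px):
        i0 = int(math.floor(cy - r)) - 1
        i1 = int(math.ceil(cy + r)) + 1
        j0 = int(math.floor(cx - r)) - 1
        j1 = int(math.ceil(cx + r)) + 1
        if not wrap:
            i0, i1 = max(i0, 0), min(i1, h - 1)
            j0, j1 = max(j0, 0), min(j1, w - 1)
        ii = np.arange(i0, i1 + 1)
        jj = np.arange(j0, j1 + 1)
        disc = (jj[None, :] - cx) ** 2 + (ii[:, None] - cy) ** 2 <= r**2
        if wrap:
            mask[np.ix_(ii % h, jj % w)] |= disc
        else:
            mask[np.ix_(ii, jj)] |= disc
    return mask


# ---------------------------------------------------------------------------
# field-of-view simulation


def simulate_fov(
    config: SimConfig,
    calibration: Calibration,
    region: Region | str,
    rng: np.random.Generator,
    fov_id: str = "fov",
    section_id: str = "",
    render: bool = True,
) -> tuple:
    """Generate one field of view and its ground truth.

    Pial-surface regions get a subpial HD band (depth per
    ``config.hd_depth_um``) at intensity ``hd_intensity`` and an LD remainder
    at ``ld_ratio * hd_intensity``; neuropil regions are uniform at the LD
    intensity. Counts are Poisson with mean intensity x zone area; positions
    honour the hard-core separation; diameters are truncated lognormal.

    With ``render=False`` the raster is skipped (returns ``None`` for the
    image) and the true area fraction is computed analytically from the disc
    diameters.
    """
    config.validate()
    region = Region(region)
    w_um = calibration.fov_width_um
    h_um = calibration.fov_height_um

    pial = is_pial(region)
    depth = hd_depth_for(region, config.hd_depth_um) if pial else None
    if pial:
        hd_area_mm2 = w_um * depth / 1e6
        ld_area_mm2 = w_um * (h_um - depth) / 1e6
        mean_hd = config.hd_intensity * hd_area_mm2
        mean_ld = config.hd_intensity * config.ld_ratio * ld_area_mm2
    else:
        mean_hd = 0.0
        mean_ld = config.hd_intensity * config.ld_ratio * calibration.fov_area_mm2

    n_hd = int(rng.poisson(mean_hd)) if mean_hd > 0 else 0
    n_ld = int(rng.poisson(mean_ld)) if mean_ld > 0 else 0

    context = f"region={region.value}, hd_intensity={config.hd_intensity}/mm^2"
    accepted: list = []
    hd_pts = (
        _place_points(
            rng, n_hd, (0.0, w_um), (0.0, depth), accepted,
            config.min_separation_um, config.max_placement_attempts, context,
        )
        if n_hd
        else []
    )
    y_lo = depth if pial else 0.0
    ld_pts = (
        _place_points(
            rng, n_ld, (0.0, w_um), (y_lo, h_um), accepted,
            config.min_separation_um, config.max_placement_attempts, context,
        )
        if n_ld
        else []
    )

    n = n_hd + n_ld
    diameters = sample_truncated_lognormal(
        rng, n, config.diameter_log_mu, config.diameter_log_sigma, config.diameter_bounds_um
    )
    xy = np.array(hd_pts + ld_pts, dtype=float).reshape(-1, 2)
    zones = np.array(["HD"] * n_hd + ["LD"] * n_ld)

    objects = pd.DataFrame(
        {
            "fov_id": fov_id,
            "section_id": section_id,
            "region": region.value,
            "object_id": np.arange(n, dtype=int),
            "centroid_x_um": xy[:, 0] if n else np.array([], dtype=float),
            "centroid_y_um": xy[:, 1] if n else np.array([], dtype=float),
            "true_diameter_um": diameters,
            "zone": zones if n else np.array([], dtype=object),
        }
    )

    image = None
    if render:
        ps = calibration.pixel_size_um
        shape = (calibration.fov_height_px, calibration.fov_width_px)
        centers_px = xy / ps - 0.5 if n else np.zeros((0, 2))
        radii_px = diameters / (2 * ps)
        disc_mask = _rasterize_discs(shape, centers_px, radii_px)
        pixels = np.full(shape, config.background_level, dtype=float)
        pixels[disc_mask] = config.blob_peak_level
        pixels += rng.normal(0.0, config.background_noise_sd, size=shape)
        pixels = np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)
        image = Micrograph(pixels=pixels, calibration=calibration, fov_id=fov_id, region=region)
        area_fraction = 100.0 * disc_mask.sum() * calibration.pixel_area_um2 / calibration.fov_area_um2
    else:
        # analytic: disc areas, ignoring clipping at the field edges
        area_fraction = 100.0 * float(np.sum(np.pi * (diameters / 2) ** 2)) / calibration.fov_area_um2

    fovs = pd.DataFrame(
        {
            "fov_id": [fov_id],
            "section_id": [section_id],
            "region": [region.value],
            "true_count": [n],
            "true_area_fraction_pct": [area_fraction],
        }
    )
    gt = GroundTruth(objects=objects, fovs=fovs, sections=GroundTruth.empty().sections)
    return image, gt


# ---------------------------------------------------------------------------
# stage model


def stage_expected_counts(stage: int) -> dict:
    """Expected per-FOV CoA counts per region for each burden stage.

    The per-FOV count bands defining the stages ([0,10), [10,50), [50,500]
    in the fimbria pial surface, treated as half-open) anchor these values;
    within a band the regional gradient decays monotonically with pial
    distance from the fimbria on both sides, and the fimbria pial surface
    always carries the most CoA. Values are kept >= 1 count away from band
    boundaries so stage recovery is unambiguous.
    """
    R = Region
    tables = {
        0: {},
        1: {R.FPS: 4.0, R.FIMBRIA: 3.0},
        2: {R.FPS: 30.0, R.PPS: 20.0, R.SPS: 14.0, R.FIMBRIA: 15.0},
        3: {
            R.FPS: 120.0, R.PPS: 80.0, R.SPS: 50.0, R.MPS: 30.0, R.LPS: 15.0,
            R.CPS: 6.0, R.APS: 40.0, R.FIMBRIA: 60.0, R.LV: 8.0, R.CA4: 4.0,
        },
        4: {
            R.FPS: 150.0, R.PPS: 100.0, R.SPS: 60.0, R.MPS: 35.0, R.LPS: 20.0,
            R.CPS: 8.0, R.APS: 50.0, R.FIMBRIA: 80.0, R.LV: 12.0, R.CA4: 6.0,
            R.CA3: 1.0, R.CA1: 1.0,
        },
    }
    if stage not in tables:
        raise ValueError("stage must be in 0..4")
    counts = {region: 0.0 for region in ALL_REGIONS}
    counts.update(tables[stage])
    return counts


def _intensity_for_count(
    expected_count: float, region: Region, config: SimConfig, calibration: Calibration
) -> float:
    """HD intensity (per mm^2) that yields the target expected per-FOV count."""
    if expected_count <= 0:
        return 0.0
    w_um = calibration.fov_width_um
    h_um = calibration.fov_height_um
    if is_pial(region):
        depth = hd_depth_for(region, config.hd_depth_um)
        hd_area = w_um * depth / 1e6
        ld_area = w_um * (h_um - depth) / 1e6
        return expected_count / (hd_area + config.ld_ratio * ld_area)
    if config.ld_ratio <= 0:
        raise ValueError("ld_ratio must be positive to populate neuropil regions")
    return expected_count / (config.ld_ratio * calibration.fov_area_mm2)


def simulate_section(
    config: SimConfig,
    calibration: Calibration,
    rng: np.random.Generator,
    section_id: str = "S000",
    regions: Sequence[Region] | None = None,
    render: bool = True,
) -> tuple:
    """Generate all fields of one brain section at ``config.stage``.

    Returns ``(images, ground_truth)`` where ``images`` maps region ->
    list of :class:`Micrograph` (or ``None`` with ``render=False``).
    Deep-white-matter involvement of the parahippocampal/fusiform gyri has no
    sampled region label, so it is emitted as a per-section annotation (true
    at stage 4); lateral-ventricle involvement follows from LV counts.
    """
    config.validate()
    counts = stage_expected_counts(config.stage)
    regions = list(regions) if regions is not None else list(ALL_REGIONS)

    images: dict = {}
    parts = []
    for region in regions:
        region = Region(region)
        cfg_r = replace(config, hd_intensity=_intensity_for_count(counts[region], region, config, calibration))
        fovs = []
        for k in range(config.fovs_per_region):
            fov_id = f"{section_id}/{region.value}/{k}"
            image, gt = simulate_fov(
                cfg_r, calibration, region, rng,
                fov_id=fov_id, section_id=section_id, render=render,
            )
            fovs.append(image)
            parts.append(gt)
        images[region] = fovs

    gt = GroundTruth.concat(parts)
    gt.sections = pd.DataFrame(
        {
            "section_id": [section_id],
            "true_stage": [config.stage],
            "deep_wm_lv": [counts[Region.LV] > 0],
            "deep_wm_phg_fusiform": [config.stage == 4],
        }
    )
    return images, gt


def simulate_cohort(
    config: SimConfig,
    calibration: Calibration = DEFAULT_CALIBRATION,
    rng: np.random.Generator | None = None,
    regions: Sequence[Region] | None = None,
    render: bool = True,
    stages: Sequence[int] | None = None,
) -> tuple:
    """Generate a cohort of sections with subject covariates.

    Ages and BMI are uniform over their configured ranges; sex is balanced.
    Stages are assigned in a balanced round-robin over 0..4 and then shuffled,
    independent of age. ``config.age_diameter_slope`` shifts each subject's
    median disc diameter by ``slope * (age - age midpoint)`` um.

    Returns ``(images_by_section, ground_truth, covariates)``.
    """
    config.validate()
    if config.subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = config.subjects
    ages = rng.uniform(*config.age_range, size=n)
    bmis = rng.uniform(*config.bmi_range, size=n)
    sexes = np.array(["M", "F"] * (n // 2 + 1))[:n]
    sexes = rng.permutation(sexes)
    if stages is None:
        stage_list = np.array([(i % 5) for i in range(n)])
        stage_list = rng.permutation(stage_list)
    else:
        stage_list = np.asarray(stages, dtype=int)
        if len(stage_list) != n:
            raise ValueError("stages must have one entry per subject")

    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])
    base_median = math.exp(config.diameter_log_mu)
    lo = config.diameter_bounds_um[0]

    images_by_section: dict = {}
    parts = []
    covs = []
    for i in range(n):
        section_id = f"S{i:03d}"
        median_i = max(base_median + config.age_diameter_slope * (ages[i] - age_mid), lo + 0.5)
        cfg_i = replace(config, stage=int(stage_list[i]), diameter_log_mu=math.log(median_i))
        images, gt = simulate_section(
            cfg_i, calibration, rng, section_id=section_id, regions=regions, render=render
        )
        images_by_section[section_id] = images
        parts.append(gt)
        covs.append(
            {
                "section_id": section_id,
                "age": ages[i],
                "bmi": bmis[i],
                "sex": sexes[i],
            }
        )

    gt = GroundTruth.concat(parts)
    covariates = pd.DataFrame(covs)
    gt.sections = gt.sections.merge(covariates, on="section_id")
    return images_by_section, gt, covariates


# ---------------------------------------------------------------------------
# ground-truth summaries and mosaics (oracle-side helpers)


def ground_truth_summaries(gt: GroundTruth, calibration: Calibration) -> pd.DataFrame:
    """Per-FOV parameter table computed directly from the generating truth.

    Mirrors the measured five-parameter summary (count, area fraction %, and
    mean/min/max diameters with empty fields as NaN) but bypasses detection,
    so staging and statistics can be exercised in isolation.
    """
    rows = []
    obj_groups = dict(tuple(gt.objects.groupby("fov_id"))) if len(gt.objects) else {}
    for _, fov in gt.fovs.iterrows():
        objs = obj_groups.get(fov["fov_id"])
        if objs is None or len(objs) == 0:
            rows.append(
                {
                    "fov_id": fov["fov_id"],
                    "section_id": fov["section_id"],
                    "region": fov["region"],
                    "count": 0,
                    "area_fraction_pct": 0.0,
                    "mean_diameter_um": np.nan,
                    "min_diameter_um": np.nan,
                    "max_diameter_um": np.nan,
                }
            )
        else:
            d = objs["true_diameter_um"].to_numpy()
            rows.append(
                {
                    "fov_id": fov["fov_id"],
                    "section_id": fov["section_id"],
                    "region": fov["region"],
                    "count": int(len(d)),
                    "area_fraction_pct": float(fov["true_area_fraction_pct"]),
                    "mean_diameter_um": float(d.mean()),
                    "min_diameter_um": float(d.min()),
                    "max_diameter_um": float(d.max()),
                }
            )
    return pd.DataFrame(rows)


def simulate_mosaic_mask(
    rng: np.random.Generator,
    tile_calibration: Calibration,
    n_tiles_x: int,
    n_tiles_y: int,
    intensity_per_mm2: float,
    config: SimConfig,
) -> tuple:
    """Binary mosaic of discs over a toroidal domain, tiled into frames.

    Discs are dropped as a hard-core process over the whole mosaic at the
    given intensity and rasterised with wrap-around, so each disc appears
    exactly once when the mosaic is cut into ``n_tiles_x * n_tiles_y`` tiles
    and counted with the left/bottom edge-exclusion rule (up to the minimum
    size filter). Returns ``(mask, n_objects)``.
    """
    ps = tile_calibration.pixel_size_um
    w_px = tile_calibration.fov_width_px * n_tiles_x
    h_px = tile_calibration.fov_height_px * n_tiles_y
    w_um, h_um = w_px * ps, h_px * ps
    area_mm2 = w_um * h_um / 1e6
    n = int(rng.poisson(intensity_per_mm2 * area_mm2))
    pts: list = []
    _place_points(
        rng, n, (0.0, w_um), (0.0, h_um), pts,
        config.min_separation_um, config.max_placement_attempts, "mosaic",
    )
    xy = np.array(pts, dtype=float).reshape(-1, 2)
    diameters = sample_truncated_lognormal(
        rng, n, config.diameter_log_mu, config.diameter_log_sigma, config.diameter_bounds_um
    )
    mask = _rasterize_discs((h_px, w_px), xy / ps - 0.5, diameters / (2 * ps), wrap=True)
    return mask, n


def tile_mosaic(mask: np.ndarray, tile_calibration: Calibration) -> list:
    """Cut a mosaic raster into per-tile arrays (row-major order)."""
    th, tw = tile_calibration.fov_height_px, tile_calibration.fov_width_px
    h, w = mask.shape
    tiles = []
    for i in range(0, h, th):
        for j in range(0, w, tw):
            tiles.append(mask[i : i + th, j : j + tw])
    return tiles
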