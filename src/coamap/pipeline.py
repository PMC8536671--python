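"""End-to-end orchestration: simulate -> detect -> quantify -> stage -> stats.

A run is driven by a :class:`RunConfig` (YAML-serialisable) and a seed; the
same config and seed reproduce every output byte for byte. Outputs are
headered UTF-8 CSVs with units embedded in column names (um for lengths,
mm^2 for areas, % for fractions), plus a manifest recording the config, the
seed, package versions, per-stage row counts and a SHA-256 digest of every
table. Each stage logs its row counts, and any failure aborts with the stage
name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import DEFAULT_CALIBRATION, Calibration
from .detection import detect, objects_to_frame
from .image import Micrograph, read_micrograph, write_micrograph
from .regions import PIAL_REGIONS, Region, is_pial
from .simulate import GroundTruth, SimConfig, simulate_cohort, simulate_section
from .staging import (
    assignments_to_frame,
    classify_stage,
    profiles_from_summaries,
    rank_sequence,
)
from .stats import (
    build_grid,
    hd_ld_tests,
    posthoc_to_frame,
    regional_parameter_table,
    regional_size_comparison,
)
from .zones import (
    ZonePartition,
    summaries_to_frame,
    summarize_fov,
    summarize_zones,
    zone_summaries_to_frame,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    subjects: int = 5
    fovs_per_region: int = 2
    alpha: float = 0.05
    detection_method: str = "otsu"
    detection_level: float | None = None
    min_diameter_um: float = 3.0
    calibration: Calibration = field(default_factory=lambda: DEFAULT_CALIBRATION)
    sim: dict = field(default_factory=dict)  # SimConfig field overrides
    images_dir: str | None = None  # read images instead of simulating
    partitions_path: str | None = None  # JSON pial-border polylines per region
    covariates_path: str | None = None
    save_images: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cal = raw.pop("calibration", None)
        cfg = cls(**raw)
        if cal:
            cfg.calibration = Calibration.from_dict(cal)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calibration"] = self.calibration.to_dict()
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _load_partitions(config: RunConfig) -> dict:
    """Per-region zone partitions: from a JSON polyline file or the straight
    top-edge default for every pial region."""
    if config.partitions_path is not None:
        path = Path(config.partitions_path)
        if not path.exists():
            raise FileNotFoundError(f"partitions file not found: {path}")
        entries = json.loads(path.read_text())
        partitions = {}
        for name, entry in entries.items():
            region = Region(name)
            partitions[region] = ZonePartition.from_border(
                region,
                config.calibration,
                entry["border"],
                hd_depth_um=entry.get("hd_depth_um"),
            )
        return partitions
    return {r: ZonePartition.straight_top_edge(r, config.calibration) for r in PIAL_REGIONS}


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": _versions(),
        "row_counts": {},
        "outputs": {},
    }
    rng = np.random.default_rng(config.seed)

    # -- simulate (or ingest) ------------------------------------------------
    stage_name = "simulate"
    try:
        if config.images_dir is not None:
            micrographs, gt, covariates = _ingest_images(config)
        else:
            sim_cfg = SimConfig(
                seed=config.seed,
                fovs_per_region=config.fovs_per_region,
                subjects=config.subjects,
                **config.sim,
            )
            images_by_section, gt, covariates = simulate_cohort(
                sim_cfg, config.calibration, rng=rng
            )
            micrographs = [
                img
                for images in images_by_section.values()
                for fovs in images.values()
                for img in fovs
                if img is not None
            ]
            if config.save_images:
                img_dir = out / "images"
                for img in micrographs:
                    write_micrograph(img, img_dir / (img.fov_id.replace("/", "_") + ".tif"))
            _write_csv(gt.objects, out / "truth_objects.csv")
            _write_csv(gt.fovs, out / "truth_fovs.csv")
            _write_csv(gt.sections, out / "truth_sections.csv")
        _write_csv(covariates, out / "covariates.csv")
        manifest["row_counts"]["micrographs"] = len(micrographs)
        logger.info("simulate: %d micrographs", len(micrographs))
    except Exception as exc:
        raise PipelineError(stage_name, str(exc)) from exc

    # -- detect --------------------------------------------------------------
    stage_name = "detect"
    try:
        all_objects = {}
        for img in micrographs:
            objs = detect(
                img,
                method=config.detection_method,
                level=config.detection_level,
                min_diameter_um=config.min_diameter_um,
            )
            all_objects[img.fov_id] = (img, objs)
        frames = [objects_to_frame(objs) for _, objs in all_objects.values()]
        frames = [f for f in frames if len(f)]
        objects_df = pd.concat(frames, ignore_index=True) if frames else objects_to_frame([])
        objects_df.insert(1, "section_id", objects_df["fov_id"].str.split("/").str[0])
        objects_df.insert(2, "region", objects_df["fov_id"].str.split("/").str[1])
        _write_csv(objects_df, out / "objects.csv")
        manifest["row_counts"]["objects"] = len(objects_df)
        logger.info("detect: %d objects in %d fields", len(objects_df), len(all_objects))
    except Exception as exc:
        raise PipelineError(stage_name, str(exc)) from exc

    # -- quantify ------------------------------------------------------------
    stage_name = "quantify"
    try:
        partitions = _load_partitions(config)
        fov_rows, zone_rows, zone_fov_ids, zone_section_ids = [], [], [], []
        fov_section_ids = []
        for fov_id, (img, objs) in all_objects.items():
            section_id = fov_id.split("/")[0]
            fov_rows.append(summarize_fov(objs, img.calibration, img.region, fov_id=fov_id))
            fov_section_ids.append(section_id)
            if is_pial(img.region):
                part = partitions[img.region]
                hd, ld = summarize_zones(objs, part)
                zone_rows.extend([hd, ld])
                zone_fov_ids.extend([fov_id, fov_id])
                zone_section_ids.extend([section_id, section_id])
        fov_summaries = summaries_to_frame(fov_rows, section_ids=fov_section_ids)
        zone_summaries = zone_summaries_to_frame(
            zone_rows, zone_fov_ids, section_ids=zone_section_ids
        )
        _write_csv(fov_summaries, out / "fov_summaries.csv")
        _write_csv(zone_summaries, out / "zone_summaries.csv")
        manifest["row_counts"]["fov_summaries"] = len(fov_summaries)
        manifest["row_counts"]["zone_summaries"] = len(zone_summaries)
        logger.info("quantify: %d FOV summaries", len(fov_summaries))
    except Exception as exc:
        raise PipelineError(stage_name, str(exc)) from exc

    # -- stage ---------------------------------------------------------------
    stage_name = "stage"
    try:
        section_flags = gt.sections if len(gt.sections) else None
        profiles = profiles_from_summaries(fov_summaries, section_flags=section_flags)
        assignments = rank_sequence([classify_stage(p) for p in profiles])
        stages_df = assignments_to_frame(assignments)
        _write_csv(stages_df, out / "stages.csv")
        manifest["row_counts"]["stages"] = len(stages_df)
        logger.info("stage: %d sections staged", len(stages_df))
    except Exception as exc:
        raise PipelineError(stage_name, str(exc)) from exc

    # -- stats ---------------------------------------------------------------
    stage_name = "stats"
    try:
        param_table = regional_parameter_table(fov_summaries)
        ranks = stages_df.set_index("section_id")["rank"].astype(float)
        covs = covariates.set_index("section_id")
        grids = []
        for name, series in (
            ("ranked_sequence", ranks),
            ("age", covs["age"] if "age" in covs else None),
            ("bmi", covs["bmi"] if "bmi" in covs else None),
        ):
            if series is None:
                continue
            grid = build_grid(param_table, series, name)
            grid.table.insert(0, "covariate", name)
            grids.append(grid.table)
        stats_grid = pd.concat(grids, ignore_index=True)
        _write_csv(stats_grid, out / "stats_grid.csv")
        hdld = hd_ld_tests(zone_summaries, alpha=config.alpha)
        _write_csv(hdld, out / "hd_ld_tests.csv")
        try:
            _, _, ph = regional_size_comparison(param_table, alpha=config.alpha)
            _write_csv(posthoc_to_frame(ph, alpha=config.alpha), out / "posthoc.csv")
        except ValueError:
            logger.info("stats: too little diameter data for the regional comparison")
        manifest["row_counts"]["stats_grid"] = len(stats_grid)
        logger.info("stats: %d grid cells", len(stats_grid))
    except Exception as exc:
        raise PipelineError(stage_name, str(exc)) from exc

    for csv in sorted(out.glob("*.csv")):
        manifest["outputs"][csv.name] = _sha256(csv)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _versions() -> dict:
    import scipy
    import skimage

    from . import __version__

    return {
        "coamap": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
    }


def _ingest_images(config: RunConfig) -> tuple:
    """Read micrographs (TIFF + sidecars) and covariates from disk."""
    img_dir = Path(config.images_dir)
    if not img_dir.exists():
        raise FileNotFoundError(f"images directory not found: {img_dir}")
    micrographs = []
    for path in sorted(img_dir.glob("*.tif")) + sorted(img_dir.glob("*.png")):
        micrographs.append(read_micrograph(path))
    if not micrographs:
        raise FileNotFoundError(f"no images found in {img_dir}")
    covariates = (
        pd.read_csv(config.covariates_path)
        if config.covariates_path
        else pd.DataFrame(columns=["section_id", "age", "bmi", "sex"])
    )
    return micrographs, GroundTruth.empty(), covariates


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Emit a small deterministic test corpus: one rendered field per stage
    for the regions the stage criteria depend on, with ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    parts = []
    hashes = {}
    for stage in range(5):
        cfg = SimConfig(seed=seed, stage=stage, fovs_per_region=1)
        images, gt = simulate_section(
            cfg,
            DEFAULT_CALIBRATION,
            rng,
            section_id=f"FIX{stage}",
            regions=[Region.FPS, Region.PPS, Region.SPS, Region.LV],
        )
        for region, fovs in images.items():
            for img in fovs:
                path = out / (img.fov_id.replace("/", "_") + ".tif")
                write_micrograph(img, path)
                hashes[path.name] = _sha256(path)
        parts.append(gt)
    gt = GroundTruth.concat(parts)
    _write_csv(gt.objects, out / "truth_objects.csv")
    _write_csv(gt.fovs, out / "truth_fovs.csv")
    _write_csv(gt.sections, out / "truth_sections.csv")
    for name in ("truth_objects.csv", "truth_fovs.csv", "truth_sections.csv"):
        hashes[name] = _sha256(out / name)
    (out / "fixture_manifest.json").write_text(json.dumps(hashes, indent=2, sort_keys=True))
    return hashes
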