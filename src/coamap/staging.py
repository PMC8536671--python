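"""Stage classification and burden ranking of whole sections.

A section's CoA burden is staged 0-4 from its regional per-FOV mean counts
and two deep-white-matter involvement flags, using half-open count bands
([0,10), [10,50), [50,500] in the fimbria pial surface; boundary counts go
to the higher stage):

* stage 4 - >= 50 CoA/FOV in the fimbria pial surface and CoA in the deep
  white matter of the parahippocampal/fusiform gyri;
* stage 3 - >= 50 CoA/FOV in the fimbria pial surface, continuous pial
  spread through prosubiculum and subiculum, and CoA in the deep white
  matter of the wall of the lateral ventricle;
* stage 2 - >= 10 CoA/FOV in the fimbria pial surface with CoA along the
  prosubiculum and subiculum pial surfaces;
* stage 1 - any CoA in the fimbria pial surface;
* stage 0 - no CoA.

A continuous burden score (sum of log1p regional mean counts over the pial
surfaces, plus bonuses of 2 and 4 for the two deep-white-matter flags)
replaces the manual lowest-to-highest ordering of sections: any strictly
monotone alternative would produce the same ranked sequence properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import PIAL_REGIONS, Region


@dataclass
class SectionProfile:
    """Regional per-FOV mean counts and spatial-extent flags of one section."""

    section_id: str
    counts: dict  # Region -> mean per-FOV count
    deep_wm_lv: bool = False
    deep_wm_phg_fusiform: bool = False

    def count(self, region: Region) -> float:
        return float(self.counts.get(region, 0.0))

    @property
    def fimbria_pial_count(self) -> float:
        return self.count(Region.FPS)


@dataclass
class StageAssignment:
    section_id: str
    stage: int
    burden_score: float
    criteria_trace: list = field(default_factory=list)
    rank: int | None = None


def burden_score(profile: SectionProfile) -> float:
    """Continuous burden score; zero iff no CoA anywhere."""
    score = sum(math.log1p(profile.count(r)) for r in PIAL_REGIONS)
    score += 2.0 * bool(profile.deep_wm_lv)
    score += 4.0 * bool(profile.deep_wm_phg_fusiform)
    return score


def classify_stage(profile: SectionProfile) -> StageAssignment:
    """Evaluate the stage decision ladder top-down."""
    fps = profile.fimbria_pial_count
    pps_sps_present = profile.count(Region.PPS) > 0 and profile.count(Region.SPS) > 0
    trace = [
        f"FPS mean count = {fps:g}",
        f"PPS-SPS pial continuity = {pps_sps_present}",
        f"deep_wm_lv = {bool(profile.deep_wm_lv)}",
        f"deep_wm_phg_fusiform = {bool(profile.deep_wm_phg_fusiform)}",
    ]
    if profile.deep_wm_phg_fusiform and fps >= 50:
        stage = 4
    elif profile.deep_wm_lv and fps >= 50 and pps_sps_present:
        stage = 3
    elif fps >= 10 and pps_sps_present:
        stage = 2
    elif fps > 0:
        stage = 1
    else:
        stage = 0
    trace.append(f"stage = {stage}")
    return StageAssignment(
        section_id=profile.section_id,
        stage=stage,
        burden_score=burden_score(profile),
        criteria_trace=trace,
    )


def rank_sequence(assignments: list) -> list:
    """Order sections from lowest to highest burden (ranks 1..n).

    Sorted ascending by burden score; ties broken by section_id, so the
    output is invariant to input order. Returns a new sorted list with the
    ``rank`` fields set.
    """
    if not assignments:
        raise ValueError("at least one section is required")
    ordered = sorted(assignments, key=lambda a: (a.burden_score, a.section_id))
    out = []
    for i, a in enumerate(ordered, start=1):
        out.append(
            StageAssignment(
                section_id=a.section_id,
                stage=a.stage,
                burden_score=a.burden_score,
                criteria_trace=list(a.criteria_trace),
                rank=i,
            )
        )
    return out


def profiles_from_summaries(
    fov_summaries: pd.DataFrame, section_flags: pd.DataFrame | None = None
) -> list:
    """Build section profiles from a per-FOV summary table.

    ``fov_summaries`` needs columns section_id, region, count. The
    lateral-ventricle deep-white-matter flag is derived from LV neuropil
    counts; parahippocampal/fusiform involvement is not among the sampled
    regions, so it is taken from ``section_flags`` (columns section_id,
    deep_wm_phg_fusiform) when provided, else False.
    """
    flags = {}
    if section_flags is not None and len(section_flags):
        flags = section_flags.set_index("section_id")["deep_wm_phg_fusiform"].to_dict()
    profiles = []
    means = (
        fov_summaries.groupby(["section_id", "region"], sort=True)["count"].mean().reset_index()
    )
    for section_id, grp in means.groupby("section_id", sort=True):
        counts = {Region(r): c for r, c in zip(grp["region"], grp["count"])}
        profiles.append(
            SectionProfile(
                section_id=str(section_id),
                counts=counts,
                deep_wm_lv=counts.get(Region.LV, 0.0) > 0,
                deep_wm_phg_fusiform=bool(flags.get(section_id, False)),
            )
        )
    return profiles


def assignments_to_frame(assignments: list) -> pd.DataFrame:
    import json

    return pd.DataFrame(
        [
            {
                "section_id": a.section_id,
                "stage": a.stage,
                "burden_score": a.burden_score,
                "rank": a.rank,
                "criteria_trace": json.dumps(a.criteria_trace),
            }
            for a in assignments
        ]
    )
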