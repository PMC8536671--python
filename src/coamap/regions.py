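"""Sampled regions of the hippocampal formation.

Fourteen regions are analysed: seven subpial sampling sites along the pial
border (ordered anatomically from the alveus, through the fimbria, to the
collateral sulcus) and seven neuropil regions surrounding the lateral
ventricle. Pial-surface fields carry a high-density (HD) subpial band whose
analysis depth is fixed per region; neuropil fields have no pial border and
are treated as low-density (LD) throughout.
"""

from __future__ import annotations

from enum import Enum


class Region(str, Enum):
    # pial (subpial) surface sampling sites
    APS = "APS"  # alveus pial surface
    FPS = "FPS"  # fimbria pial surface
    PPS = "PPS"  # prosubiculum pial surface
    SPS = "SPS"  # subiculum pial surface
    MPS = "MPS"  # medial entorhinal cortex pial surface
    LPS = "LPS"  # lateral entorhinal cortex pial surface
    CPS = "CPS"  # collateral sulcus pial surface
    # neuropil regions
    LV = "LV"  # wall of the lateral ventricle
    FIMBRIA = "fimbria"
    CA4 = "CA4"
    CA3 = "CA3"
    CA2 = "CA2"
    CA1 = "CA1"
    SUBICULUM = "subiculum"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Pial sampling sites in anatomical order along the pial border.
PIAL_REGIONS: tuple[Region, ...] = (
    Region.APS,
    Region.FPS,
    Region.PPS,
    Region.SPS,
    Region.MPS,
    Region.LPS,
    Region.CPS,
)

NEUROPIL_REGIONS: tuple[Region, ...] = (
    Region.LV,
    Region.FIMBRIA,
    Region.CA4,
    Region.CA3,
    Region.CA2,
    Region.CA1,
    Region.SUBICULUM,
)

ALL_REGIONS: tuple[Region, ...] = PIAL_REGIONS + NEUROPIL_REGIONS

#: Fixed HD-zone analysis depth (um below the pial border) per pial region.
HD_DEPTH_UM: dict[Region, float] = {
    Region.FPS: 100.0,
    Region.PPS: 70.0,
    Region.APS: 40.0,
    Region.SPS: 40.0,
    Region.MPS: 40.0,
    Region.LPS: 40.0,
    Region.CPS: 40.0,
}

#: Ordinal pial distance from the fimbria pial surface, used to express the
#: bilateral density decay (alveus on one side; prosubiculum -> collateral
#: sulcus on the other).
PIAL_DISTANCE_FROM_FPS: dict[Region, int] = {
    Region.FPS: 0,
    Region.APS: 1,
    Region.PPS: 1,
    Region.SPS: 2,
    Region.MPS: 3,
    Region.LPS: 4,
    Region.CPS: 5,
}


def is_pial(region: Region | str) -> bool:
    return Region(region) in PIAL_REGIONS


def hd_depth_for(region: Region | str, overrides: dict | None = None) -> float | None:
    """HD-zone depth for a region, or None for neuropil regions."""
    region = Region(region)
    if region not in PIAL_REGIONS:
        return None
    if overrides and region in overrides:
        return float(overrides[region])
    return HD_DEPTH_UM[region]
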