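"""Physical calibration of a field of view (FOV).

A micrograph is analysed in physical units: lengths in micrometres (um) and
areas in square millimetres (mm^2). The default geometry reproduces the
acquisition setup the pipeline targets: 1600 x 1200 px fields covering
0.2 mm^2, i.e. a pixel side of sqrt(0.2e6 / (1600*1200)) ~= 0.32275 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Calibration:
    """Pixel size and raster dimensions of one field of view.

    Parameters
    ----------
    pixel_size_um : float
        Length of one (square) pixel side in micrometres.
    fov_width_px, fov_height_px : int
        Raster dimensions in pixels.
    """

    pixel_size_um: float
    fov_width_px: int
    fov_height_px: int

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.fov_width_px <= 0 or self.fov_height_px <= 0:
            raise ValueError("FOV dimensions must be positive integers")

    @classmethod
    def from_fov_area(cls, width_px: int, height_px: int, area_mm2: float) -> "Calibration":
        """Build a calibration from raster dimensions and total FOV area."""
        pixel_size = math.sqrt(area_mm2 * 1e6 / (width_px * height_px))
        return cls(pixel_size_um=pixel_size, fov_width_px=width_px, fov_height_px=height_px)

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    @property
    def fov_width_um(self) -> float:
        return self.fov_width_px * self.pixel_size_um

    @property
    def fov_height_um(self) -> float:
        return self.fov_height_px * self.pixel_size_um

    @property
    def fov_area_um2(self) -> float:
        return self.fov_width_px * self.fov_height_px * self.pixel_area_um2

    @property
    def fov_area_mm2(self) -> float:
        return self.fov_area_um2 / 1e6

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "fov_width_px": self.fov_width_px,
            "fov_height_px": self.fov_height_px,
            "fov_area_mm2": self.fov_area_mm2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            pixel_size_um=float(d["pixel_size_um"]),
            fov_width_px=int(d["fov_width_px"]),
            fov_height_px=int(d["fov_height_px"]),
        )


#: Default acquisition geometry: 1600 x 1200 px covering 0.2 mm^2.
DEFAULT_CALIBRATION = Calibration.from_fov_area(1600, 1200, 0.2)
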