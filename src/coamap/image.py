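"""Micrograph container and on-disk format.

Images are single-channel TIFFs (16-bit by convention) with the physical
calibration recorded in a JSON sidecar next to the image
(``<name>.json`` for ``<name>.tif``). Pixel (i, j) has its centre at
``x = (j + 0.5) * pixel_size_um``, ``y = (i + 0.5) * pixel_size_um`` with the
origin in the top-left corner, x rightward and y downward. In synthetic
pial-surface fields the pial border is the top image edge, so y is the depth
below the pia.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .calibration import Calibration
from .regions import Region


@dataclass
class Micrograph:
    """One calibrated grayscale field of view."""

    pixels: np.ndarray
    calibration: Calibration
    fov_id: str = ""
    region: Region | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        h, w = self.pixels.shape
        if (w, h) != (self.calibration.fov_width_px, self.calibration.fov_height_px):
            raise ValueError(
                f"image shape {self.pixels.shape} does not match calibration "
                f"({self.calibration.fov_height_px}, {self.calibration.fov_width_px})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")


def write_micrograph(image: Micrograph, path: str | Path) -> Path:
    """Write a micrograph as TIFF plus a calibration sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels)
    sidecar = {
        **image.calibration.to_dict(),
        "fov_id": image.fov_id,
        "region": image.region.value if image.region is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_micrograph(path: str | Path) -> Micrograph:
    """Read a TIFF (or PNG) micrograph with its calibration sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"calibration sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    pixels = tifffile.imread(path) if path.suffix.lower() in {".tif", ".tiff"} else None
    if pixels is None:
        import imageio.v3 as iio

        pixels = np.asarray(iio.imread(path))
    region = Region(sidecar["region"]) if sidecar.get("region") else None
    return Micrograph(
        pixels=np.asarray(pixels),
        calibration=Calibration.from_dict(sidecar),
        fov_id=sidecar.get("fov_id", path.stem),
        region=region,
    )
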