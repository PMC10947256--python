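"""Vein-length and vein-density measurement.

On the final trimmed skeleton every vein is a one-pixel-wide line, so the
foreground pixel count estimates total vein length: each pixel contributes
one pixel-side of length. With a pixel side of ``pixel_length_um``
micrometres,

    vein_length_um  = pixel_count * pixel_length_um
    area_mm2        = height * width * pixel_length_um^2 * 1e-6
    density         = vein_length_um / area_mm2      (um mm^-2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig

__all__ = ["DensityResult", "measure_density"]


@dataclass(frozen=True)
class DensityResult:
    """Per-image vein density record, one row of the results table."""

    image_id: str
    skeleton_pixel_count: int
    vein_length_um: float
    area_mm2: float
    vein_density_um_per_mm2: float
    auto_trim_used: bool = False
    effective_trim_factor: int = 0
    flagged: bool = False


def measure_density(skeleton: np.ndarray, config: PipelineConfig, *,
                    image_id: str = "", auto_trim_used: bool = False,
                    effective_trim_factor: int | None = None,
                    flagged: bool = False) -> DensityResult:
    """Convert a trimmed skeleton into a density measurement.

    The area always describes the measured raster: the skeleton's actual
    dimensions are used, and if they differ from the configured
    ``y_pixels`` x ``x_pixels`` the result is flagged (a batch is never
    aborted by one mis-sized image). An empty skeleton yields density 0,
    flagged.
    """
    skeleton = np.asarray(skeleton).astype(bool)
    height, width = skeleton.shape
    count = int(skeleton.sum())
    px = config.pixel_length_um
    length_um = count * px
    area_mm2 = height * width * px * px * 1e-6
    if (height, width) != (config.y_pixels, config.x_pixels):
        flagged = True
    if count == 0:
        flagged = True
    return DensityResult(
        image_id=image_id,
        skeleton_pixel_count=count,
        vein_length_um=length_um,
        area_mm2=area_mm2,
        vein_density_um_per_mm2=length_um / area_mm2,
        auto_trim_used=auto_trim_used,
        effective_trim_factor=(config.trim_factor if effective_trim_factor is None
                               else int(effective_trim_factor)),
        flagged=flagged,
    )
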