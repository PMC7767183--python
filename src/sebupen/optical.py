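"""Optical method: layer heights from tube images and cylinder volumes.

The reacted (saponified) layer appears as a bright band between the darker
intact sebum below and the solution above.  Layer heights are measured in
pixel rows on a calibrated image (default 50 px/mm, i.e. 0.02 mm per
pixel), aggregated across columns by median, and converted to mm last so
there is a single rounding point.  Volumes follow from the tube cross
section, V = pi r^2 h.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "TubeGeometry",
    "PixelCalibration",
    "LayerHeights",
    "TubeImage",
    "cylinder_volume",
    "heights_from_pixels",
    "measure_layer_heights",
    "heights_to_volumes",
]

# default intensity thresholds separating the three zones
DARK_THRESHOLD = 60.0  # intact sebum below this
BRIGHT_THRESHOLD = 180.0  # reacted band above this; solution in between


@dataclass(frozen=True)
class TubeGeometry:
    """Reaction tube geometry: 16 mm diameter, ~20 mm sebum column."""

    radius_mm: float = 8.0
    sebum_column_height_mm: float = 20.0

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("radius must be positive")
        if self.sebum_column_height_mm < 0:
            raise ValueError("sebum column height must be non-negative")

    @property
    def cross_section_mm2(self) -> float:
        return math.pi * self.radius_mm**2


@dataclass(frozen=True)
class PixelCalibration:
    """Image scale; the default 50 px/mm gives 0.02 mm per pixel."""

    pixels_per_mm: float = 50.0

    def __post_init__(self) -> None:
        if not self.pixels_per_mm > 0:
            raise ValueError("pixels_per_mm must be positive")

    @property
    def mm_per_pixel(self) -> float:
        return 1.0 / self.pixels_per_mm


@dataclass(frozen=True)
class LayerHeights:
    """Measured layer heights relative to the initial sebum level.

    ``penetration_depth_mm`` is how far the reacted layer extends below the
    initial level (etching depth); ``increase_height_mm`` is how far the
    products rise above it.  ``band_detected`` is False when no bright
    reacted band was found (both heights are then 0).
    """

    penetration_depth_mm: float
    increase_height_mm: float
    band_detected: bool = True

    def __post_init__(self) -> None:
        if self.penetration_depth_mm < 0 or self.increase_height_mm < 0:
            raise ValueError("layer heights must be non-negative")


@dataclass(frozen=True)
class TubeImage:
    """Grayscale raster of the tube column with a known baseline row.

    ``baseline_row`` is the pixel row of the initial sebum surface; rows
    increase downward (row 0 at the top).
    """

    pixels: np.ndarray  # (rows, cols), intensities 0-255
    baseline_row: int
    calibration: PixelCalibration = field(default_factory=PixelCalibration)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("image must be a 2-D array")
        if not (0 <= self.baseline_row < px.shape[0]):
            raise ValueError("baseline_row outside image")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @classmethod
    def from_png(
        cls, path: Union[str, Path], baseline_row: int,
        calibration: PixelCalibration = PixelCalibration(),
    ) -> "TubeImage":
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
        return cls(pixels=arr, baseline_row=baseline_row, calibration=calibration)

    def to_png(self, path: Union[str, Path]) -> None:
        Image.fromarray(self.pixels.astype(np.uint8), mode="L").save(path)


def cylinder_volume(h: float, geometry: TubeGeometry) -> float:
    """Cylinder volume V = pi r^2 h, in mm^3 for h in mm."""
    if h < 0:
        raise ValueError(f"height must be non-negative, got {h}")
    return geometry.cross_section_mm2 * h


def heights_from_pixels(
    pixel_counts: Union[float, Sequence[float], np.ndarray],
    calibration: PixelCalibration,
) -> Union[float, np.ndarray]:
    """Convert pixel heights to mm: mm = pixels / pixels_per_mm."""
    counts = np.asarray(pixel_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("pixel counts must be non-negative")
    mm = counts / calibration.pixels_per_mm
    return float(mm) if mm.ndim == 0 else mm


def _lower_median(values: np.ndarray) -> float:
    """Median with even-count ties broken toward the smaller value.

    Smaller pixel counts are boundaries closer to the baseline, so the tie
    break is 'toward the baseline'.
    """
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def _scan_band(profile: np.ndarray, dark: float, bright: float) -> int:
    """Length in pixels of the bright band at the start of ``profile``.

    ``profile`` starts at the baseline and runs away from it.  Returns 0
    when the first pixel is not bright (no band on this side).  Raises if
    the band terminates in an intensity inconsistent with the expected
    zone ordering or runs off the image edge.
    """
    if profile.size == 0 or profile[0] <= bright:
        return 0
    not_bright = profile <= bright
    if not not_bright.any():
        raise ValueError("bright band reaches the image edge; heights exceed frame")
    return int(np.argmax(not_bright))


def measure_layer_heights(
    image: TubeImage,
    dark_threshold: float = DARK_THRESHOLD,
    bright_threshold: float = BRIGHT_THRESHOLD,
) -> LayerHeights:
    """Measure penetration depth and increase height from a tube image.

    Per column, the boundary is the first row crossing the bright
    threshold scanning away from the baseline: downward the band must end
    in dark intact sebum, upward in mid-intensity solution.  The per-column
    pixel counts are aggregated by median (ties toward the baseline) and
    converted to mm through the calibration.

    Returns zero heights with ``band_detected=False`` when no bright band
    is present; raises ``ValueError`` when the zone ordering is not
    solution / bright band / dark sebum.
    """
    px = np.asarray(image.pixels, dtype=float)
    b = image.baseline_row
    n_cols = px.shape[1]
    pen = np.empty(n_cols)
    inc = np.empty(n_cols)
    for c in range(n_cols):
        down = px[b:, c]
        up = px[:b, c][::-1]  # row b-1 first
        pen_px = _scan_band(down, dark_threshold, bright_threshold)
        if pen_px > 0 and down[pen_px] >= dark_threshold:
            raise ValueError(
                "non-monotone zone ordering: bright band below the baseline "
                "does not terminate in dark sebum"
            )
        inc_px = _scan_band(up, dark_threshold, bright_threshold)
        if inc_px > 0 and up[inc_px] < dark_threshold:
            raise ValueError(
                "non-monotone zone ordering: bright band above the baseline "
                "terminates in dark sebum instead of solution"
            )
        pen[c] = pen_px
        inc[c] = inc_px
    if not (pen.any() or inc.any()):
        logger.warning("no bright reacted band detected; returning zero heights")
        return LayerHeights(0.0, 0.0, band_detected=False)
    return LayerHeights(
        penetration_depth_mm=heights_from_pixels(
            _lower_median(pen), image.calibration
        ),
        increase_height_mm=heights_from_pixels(_lower_median(inc), image.calibration),
    )


def heights_to_volumes(
    heights: LayerHeights, geometry: TubeGeometry
) -> Tuple[float, float]:
    """(penetrated, increased) volumes in mm^3 from the two layer heights."""
    return (
        cylinder_volume(heights.penetration_depth_mm, geometry),
        cylinder_volume(heights.increase_height_mm, geometry),
    )
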