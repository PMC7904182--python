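"""Background-relative intensity quantification.

Implements the reporter-intensity measurements used for necrotic-cell
scoring in *C. elegans* touch neurons:

* ``measure_region`` — total signal and pixel area inside a polygon ROI;
* ``annulus_unit_intensity`` — the unit PS intensity of the "donut" between
  two nested polygons, ``UPS = (S_outer - S_inner) / (A_outer - A_inner)``;
* ``relative_intensity`` — a unit intensity divided by the unit intensity of
  a nearby background region; 1 means no enrichment over background.

The same relative formula covers both channels: the membrane PS reporter
(annulus unit intensity over background unit intensity, RPS) and the
cytoplasmic Ca2+ reporter (cell-body signal over an equal-area background
region, Ca_R). Ratios are taken on raw intensities, not background-subtracted
ones, so adding a constant offset to an image changes them; multiplying the
whole image by a positive constant does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AnnulusROI, Polygon

__all__ = [
    "RegionMeasurement",
    "RelativeIntensity",
    "measure_region",
    "annulus_unit_intensity",
    "relative_intensity",
    "ca_relative_intensity",
    "ps_relative_intensity",
]


@dataclass(frozen=True)
class RegionMeasurement:
    """Summed pixel signal, pixel count, and their ratio for one ROI."""

    total_signal: float
    area: int
    unit_intensity: float


@dataclass(frozen=True)
class RelativeIntensity:
    """Dimensionless background-relative intensity (RPS or Ca_R)."""

    value: float
    numerator_unit: float
    background_unit: float


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    return image.astype(float, copy=False)


def measure_region(image: np.ndarray, roi: Polygon) -> RegionMeasurement:
    """Sum pixel values whose centers fall inside the polygon.

    Raises
    ------
    ValueError
        If the polygon extends beyond the image or selects no pixels.
    """
    image = _check_image(image)
    if not roi.within_image(image.shape):
        raise ValueError("polygon extends outside the image bounds")
    mask = roi.mask(image.shape)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("polygon rasterizes to zero pixels")
    total = float(image[mask].sum())
    return RegionMeasurement(total_signal=total, area=area, unit_intensity=total / area)


def annulus_unit_intensity(image: np.ndarray, roi: AnnulusROI) -> float:
    """Unit intensity of the ring between the outer and inner polygons."""
    outer = measure_region(image, roi.outer)
    inner = measure_region(image, roi.inner)
    ring_area = outer.area - inner.area
    if ring_area <= 0:
        raise ValueError("annulus has non-positive pixel area (outer must exceed inner)")
    return (outer.total_signal - inner.total_signal) / ring_area


def relative_intensity(
    target_unit: float, background: RegionMeasurement | float
) -> RelativeIntensity:
    """Divide a unit intensity by the background unit intensity."""
    bg_unit = background.unit_intensity if isinstance(background, RegionMeasurement) else float(background)
    if bg_unit <= 0:
        raise ValueError("background unit intensity must be positive")
    return RelativeIntensity(
        value=target_unit / bg_unit, numerator_unit=float(target_unit), background_unit=bg_unit
    )


def ca_relative_intensity(
    image: np.ndarray, cell: Polygon, background: Polygon
) -> RelativeIntensity:
    """Relative cytoplasmic Ca2+ intensity: cell-body unit signal over an
    equal-area nearby background region's unit signal."""
    cell_m = measure_region(image, cell)
    bg_m = measure_region(image, background)
    return relative_intensity(cell_m.unit_intensity, bg_m)


def ps_relative_intensity(
    image: np.ndarray, annulus: AnnulusROI, background: Polygon
) -> RelativeIntensity:
    """Relative surface-PS intensity: annulus unit signal over background."""
    ups = annulus_unit_intensity(image, annulus)
    bg_m = measure_region(image, background)
    return relative_intensity(ups, bg_m)
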