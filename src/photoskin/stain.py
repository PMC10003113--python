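"""Immunostain color-index quantification on section images.

The procedure mirrors the classic GIMP/ImageJ recipe for chromogenic stains:
select the stain-colored pixels (a contiguous hue band with a minimum
saturation), histogram the selection over 255 hue categories, sum the counts
in the stain peak, and divide by the region-of-interest surface area to get a
*color index* in [0, 1].  Condition indices are expressed as a percentage of
the stressed control.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import color as skcolor

from photoskin.images import RasterImage
from photoskin.synth.stain import DEFAULT_MIN_SATURATION, DEFAULT_STAIN_BAND

N_HUE_BINS = 255


@dataclasses.dataclass(frozen=True)
class ColorIndexResult:
    roi_area_px: int
    roi_area_um2: float | None
    sum_count: int
    color_index: float
    percent_of_control: float | None
    hue_band: tuple[float, float]
    min_saturation: float


def _as_rgb_float(image: RasterImage | np.ndarray) -> np.ndarray:
    px = image.pixels if isinstance(image, RasterImage) else image
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected a 3-channel image")
    px = np.asarray(px, dtype=float)
    if px.max() > 1.0:
        px = px / 255.0
    return px


def select_stain_pixels(
    image: RasterImage | np.ndarray,
    hue_band: tuple[float, float] = DEFAULT_STAIN_BAND,
    min_saturation: float = DEFAULT_MIN_SATURATION,
) -> np.ndarray:
    """Mask of pixels whose hue lies in ``hue_band`` with enough saturation.

    Hues are fractions of the hue circle in [0, 1); a band with
    ``lo > hi`` wraps around 1.0 (red).  An empty band is an error.
    """
    lo, hi = hue_band
    if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
        raise ValueError("hue band bounds must lie in [0, 1]")
    if lo == hi:
        raise ValueError("empty hue band")
    hsv = skcolor.rgb2hsv(_as_rgb_float(image))
    hue, sat = hsv[..., 0], hsv[..., 1]
    in_band = (hue >= lo) & (hue <= hi) if lo < hi else (hue >= lo) | (hue <= hi)
    return in_band & (sat >= min_saturation)


def color_histogram(
    image: RasterImage | np.ndarray,
    mask: np.ndarray | None = None,
    n_bins: int = N_HUE_BINS,
) -> np.ndarray:
    """Hue histogram (``n_bins`` equal categories over the hue circle).

    Restricted to ``mask`` when given; the counts always sum to the mask
    pixel count (conservation).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    hsv = skcolor.rgb2hsv(_as_rgb_float(image))
    hue = hsv[..., 0]
    if mask is not None:
        hue = hue[np.asarray(mask, dtype=bool)]
    counts, _ = np.histogram(hue.ravel(), bins=n_bins, range=(0.0, 1.0))
    return counts


def peak_bins_for_band(hue_band: tuple[float, float], n_bins: int = N_HUE_BINS) -> np.ndarray:
    """Indices of the hue bins whose centers fall inside ``hue_band``."""
    centers = (np.arange(n_bins) + 0.5) / n_bins
    lo, hi = hue_band
    sel = (centers >= lo) & (centers <= hi) if lo < hi else (centers >= lo) | (centers <= hi)
    return np.flatnonzero(sel)


def color_index(
    counts: np.ndarray,
    peak_bins: np.ndarray,
    roi_area_px: int,
    *,
    pixel_size: float | None = None,
    hue_band: tuple[float, float] = DEFAULT_STAIN_BAND,
    min_saturation: float = DEFAULT_MIN_SATURATION,
) -> ColorIndexResult:
    """Sum the histogram counts over the stain peak and divide by the ROI area."""
    counts = np.asarray(counts)
    peak_bins = np.asarray(peak_bins, dtype=int)
    if roi_area_px <= 0:
        raise ValueError("ROI area must be positive")
    if peak_bins.size and (peak_bins.min() < 0 or peak_bins.max() >= counts.size):
        raise ValueError("peak bins outside the histogram")
    sum_count = int(counts[peak_bins].sum())
    return ColorIndexResult(
        roi_area_px=int(roi_area_px),
        roi_area_um2=(roi_area_px * pixel_size**2) if pixel_size else None,
        sum_count=sum_count,
        color_index=sum_count / roi_area_px,
        percent_of_control=None,
        hue_band=hue_band,
        min_saturation=min_saturation,
    )


def normalize_to_control(index: float, control_index: float) -> float:
    """Express a color index as a percentage of the stressed control condition."""
    if control_index <= 0:
        raise ValueError("control index must be positive")
    return 100.0 * index / control_index


def quantify_section(
    image: RasterImage | np.ndarray,
    roi: np.ndarray,
    *,
    hue_band: tuple[float, float] = DEFAULT_STAIN_BAND,
    min_saturation: float = DEFAULT_MIN_SATURATION,
    control_index: float | None = None,
    pixel_size: float | None = None,
) -> ColorIndexResult:
    """Full section chain: select stain pixels in the ROI, histogram, index.

    The ROI is a manually supplied mask (no automatic dermis segmentation).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    stain_mask = select_stain_pixels(image, hue_band, min_saturation) & roi
    counts = color_histogram(image, stain_mask)
    result = color_index(
        counts,
        peak_bins_for_band(hue_band),
        int(roi.sum()),
        pixel_size=pixel_size,
        hue_band=hue_band,
        min_saturation=min_saturation,
    )
    if control_index is not None:
        result = dataclasses.replace(
            result, percent_of_control=normalize_to_control(result.color_index, control_index)
        )
    return result
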