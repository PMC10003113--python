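"""Synthetic stained tissue sections with a known stained-pixel fraction.

Emulates chromogenic immunostaining (violet/pink peroxidase substrate) of a
section: inside a region of interest (the "dermis"), an exact fraction ``f``
of pixels is drawn in the stain hue band (pink/magenta, high saturation) and
the rest in a pale low-saturation background tone, then converted to 8-bit
RGB.  ``f`` equals stained-pixels / ROI-pixels exactly by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import color as skcolor

from photoskin.images import RasterImage

#: default stain hue band (fraction of the hue circle): magenta-pink
DEFAULT_STAIN_BAND = (0.82, 0.96)
#: minimum saturation for a pixel to count as stained
DEFAULT_MIN_SATURATION = 0.15


@dataclasses.dataclass(frozen=True)
class StainTruth:
    roi: np.ndarray  # bool mask of the region of interest
    stained_fraction: float  # exact f in the noise-free rendering
    hue_band: tuple[float, float]
    stained_mask: np.ndarray  # bool mask of the stained pixels
    seed: int


def default_roi(shape: tuple[int, int]) -> np.ndarray:
    """Lower-half ROI, standing in for a manually outlined dermis."""
    roi = np.zeros(shape, dtype=bool)
    roi[shape[0] // 2 :, :] = True
    return roi


def gen_stain_image(
    *,
    f: float,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    roi: np.ndarray | None = None,
    hue_band: tuple[float, float] = DEFAULT_STAIN_BAND,
    pixel_size: float = 1.0,
) -> tuple[RasterImage, StainTruth]:
    """Render a 3-channel section image with stained fraction ``f`` in the ROI.

    The stained pixel count is ``round(f * roi_pixels)`` drawn uniformly at
    random inside the ROI; stained pixels get hues inside ``hue_band`` (with a
    small interior margin so 8-bit quantization cannot push them out) and
    saturations well above the selection minimum, background pixels a pale
    tone far outside the band.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("stained fraction f must lie in [0, 1]")
    if roi is None:
        roi = default_roi(shape)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != tuple(shape):
        raise ValueError("roi shape must match image shape")
    if not roi.any():
        raise ValueError("empty ROI")

    rng = np.random.default_rng(seed)
    roi_idx = np.flatnonzero(roi.ravel())
    n_stain = round(f * roi_idx.size)
    stained_flat = rng.choice(roi_idx, size=n_stain, replace=False)

    hsv = np.empty(shape + (3,), dtype=float)
    # pale tan background, saturation below the stain selection minimum
    hsv[..., 0] = 0.10
    hsv[..., 1] = 0.05
    hsv[..., 2] = 0.92

    margin = 0.02 * (hue_band[1] - hue_band[0])
    hues = rng.uniform(hue_band[0] + margin, hue_band[1] - margin, size=n_stain)
    sats = rng.uniform(0.45, 0.85, size=n_stain)
    vals = rng.uniform(0.55, 0.90, size=n_stain)
    flat = hsv.reshape(-1, 3)
    flat[stained_flat, 0] = hues
    flat[stained_flat, 1] = sats
    flat[stained_flat, 2] = vals

    rgb = (skcolor.hsv2rgb(hsv) * 255.0).round().astype(np.uint8)
    stained_mask = np.zeros(shape, dtype=bool)
    stained_mask.ravel()[stained_flat] = True

    truth = StainTruth(
        roi=roi,
        stained_fraction=n_stain / roi_idx.size,
        hue_band=hue_band,
        stained_mask=stained_mask,
        seed=seed,
    )
    return RasterImage(pixels=rgb, pixel_size=pixel_size), truth
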