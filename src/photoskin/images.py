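"""Raster image container and TIFF/JSON sidecar I/O.

Every imaging stage in the package exchanges a :class:`RasterImage`: a pixel
grid (single-channel for fluorescence, 3-channel RGB for stained sections)
with a physical pixel size in micrometres per pixel.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile


@dataclasses.dataclass(frozen=True)
class RasterImage:
    """A 2-D image with physical calibration.

    Parameters
    ----------
    pixels:
        Array of shape ``(H, W)`` (single channel) or ``(H, W, 3)`` (RGB).
    pixel_size:
        Physical side of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-channel image, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("3-D images must have exactly 3 channels (H, W, 3)")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def field_of_view(self) -> tuple[float, float]:
        """Physical image extent (height, width) in micrometres."""
        return (self.pixels.shape[0] * self.pixel_size, self.pixels.shape[1] * self.pixel_size)


def write_image(path: str | Path, image: RasterImage) -> None:
    """Write a TIFF with the pixel size recorded in the ImageJ-style metadata."""
    path = Path(path)
    tifffile.imwrite(
        path,
        image.pixels,
        metadata={"unit": "um", "pixel_size_um": image.pixel_size},
    )


def read_image(path: str | Path, pixel_size: float | None = None) -> RasterImage:
    """Read a TIFF written by :func:`write_image`.

    ``pixel_size`` overrides the value stored in the file; it is required when
    the file carries no calibration.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        if pixel_size is None:
            meta = tif.imagej_metadata or tif.shaped_metadata and tif.shaped_metadata[0] or {}
            pixel_size = meta.get("pixel_size_um") if isinstance(meta, dict) else None
    if pixel_size is None:
        raise ValueError(f"{path} carries no pixel size; pass pixel_size explicitly")
    return RasterImage(pixels=pixels, pixel_size=float(pixel_size))


def write_truth_sidecar(path: str | Path, truth: object) -> None:
    """Serialize a ground-truth dataclass next to its image as JSON."""
    path = Path(path)

    def _default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path.write_text(json.dumps(truth, default=_default, indent=1))
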