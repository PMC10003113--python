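"""Cell spreading on micropatterns: per-cell area and percent spread.

A cell is *correctly spread* when its measured area strictly exceeds the
spreading threshold (1800 um^2 by default); blue-light-stressed cells
contract and fall below it.  Holes inside the F-actin footprint are filled
before measuring, because spreading area is the cell footprint, not the
stained skeleton.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters as skfilters

from photoskin.images import RasterImage
from photoskin.synth.micropattern import SpreadTruth

#: area above which a cell counts as correctly spread (um^2)
SPREAD_THRESHOLD_UM2 = 1800.0


@dataclasses.dataclass
class CellRecord:
    cell_id: int
    pattern_id: int
    area_um2: float | None
    spread: bool | None
    centroid_um: tuple[float, float]
    n_pixels: int


def cell_area(mask: np.ndarray, pixel_size: float) -> float:
    """Area of a binary cell mask: foreground pixel count x pixel_size^2 (um^2)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return float(mask.sum()) * pixel_size**2


def detect_cells(
    image: RasterImage,
    layout: SpreadTruth | np.ndarray,
    *,
    threshold: float | None = None,
    min_size_px: int = 25,
) -> tuple[list[CellRecord], list[dict]]:
    """Assign connected F-actin components to micropattern positions.

    ``layout`` provides the pattern centers (um) either as a
    :class:`SpreadTruth` or an ``(n, 2)`` array.  Each pattern must contain
    exactly one connected cell; patterns with zero or several components are
    excluded, with the reason logged in the second return value.  Component
    holes are filled before area measurement; components below ``min_size_px``
    pixels are dropped as debris (single-pixel noise excursions above the
    threshold are not cells).
    """
    if isinstance(layout, SpreadTruth):
        centers = np.asarray(layout.centers, dtype=float)
        pattern_ids = np.asarray(layout.pattern_ids)
        pitch = layout.pitch
    else:
        centers = np.asarray(layout, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValueError("pattern layout must be an (n, 2) array of centers in um")
        pattern_ids = np.arange(len(centers))
        pitch = None

    px = image.pixels.astype(float)
    if threshold is None:
        threshold = skfilters.threshold_otsu(px) if px.max() > px.min() else np.inf
    mask = ndi.binary_fill_holes(px > threshold)
    labels, n_components = ndi.label(mask)

    if len(centers) == 0:
        return [], (
            [{"component": int(i), "reason": "no pattern layout position"} for i in range(1, n_components + 1)]
        )
    if pitch is None:
        diffs = np.diff(np.sort(centers[:, 1]))
        pitch = float(diffs[diffs > 0].min()) if (diffs > 0).any() else np.inf

    # assign each component to the nearest pattern center
    comp_centroids = ndi.center_of_mass(mask, labels, index=range(1, n_components + 1))
    per_pattern: dict[int, list[tuple[int, tuple[float, float], int]]] = {int(p): [] for p in pattern_ids}
    exclusions: list[dict] = []
    counts = np.bincount(labels.ravel())
    for comp, (r, c) in enumerate(comp_centroids, start=1):
        if counts[comp] < min_size_px:
            continue  # debris
        centroid_um = (r * image.pixel_size, c * image.pixel_size)
        dists = np.hypot(centers[:, 0] - centroid_um[0], centers[:, 1] - centroid_um[1])
        nearest = int(np.argmin(dists))
        if dists[nearest] > pitch / 2.0:
            exclusions.append({"component": comp, "reason": "off-pattern component"})
            continue
        per_pattern[int(pattern_ids[nearest])].append((comp, centroid_um, int(counts[comp])))

    records: list[CellRecord] = []
    for pid in sorted(per_pattern):
        members = per_pattern[pid]
        if len(members) == 0:
            exclusions.append({"pattern_id": pid, "reason": "no cell on pattern"})
        elif len(members) > 1:
            exclusions.append({"pattern_id": pid, "reason": f"{len(members)} cells on pattern"})
        else:
            comp, centroid_um, n_pixels = members[0]
            records.append(
                CellRecord(
                    cell_id=comp,
                    pattern_id=pid,
                    area_um2=n_pixels * image.pixel_size**2,
                    spread=None,
                    centroid_um=centroid_um,
                    n_pixels=n_pixels,
                )
            )
    return records, exclusions


def spreading_metrics(
    records: list[CellRecord] | np.ndarray,
    threshold: float = SPREAD_THRESHOLD_UM2,
) -> tuple[float, float]:
    """Mean cell area (um^2) and percentage of correctly spread cells.

    A cell counts as spread only when its area *strictly exceeds* the
    threshold; a cell at exactly the threshold is not spread.
    """
    if isinstance(records, (list, tuple)):
        areas = np.array([r.area_um2 for r in records], dtype=float)
    else:
        areas = np.asarray(records, dtype=float)
    if areas.size == 0:
        raise ValueError("spreading_metrics requires at least one cell")
    if np.isnan(areas).any():
        raise ValueError("records contain unmeasured areas")
    mean_area = float(areas.mean())
    pct_spread = 100.0 * float((areas > threshold).sum()) / areas.size
    return mean_area, pct_spread


def flag_spread(records: list[CellRecord], threshold: float = SPREAD_THRESHOLD_UM2) -> list[CellRecord]:
    """Populate each record's ``spread`` flag (strict > threshold)."""
    for r in records:
        r.spread = bool(r.area_um2 is not None and r.area_um2 > threshold)
    return records


def records_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
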