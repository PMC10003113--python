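"""Synthetic single-cell mitochondrial filament networks.

A cell's network is drawn as ``n_trees`` disjoint trees sharing a fixed total
length budget, so the *fragmentation* parameter maps monotonically onto the
tree count: ``fragmentation = 0`` gives exactly one tree holding the whole
budget, ``fragmentation = 1`` gives ``n_trees_max`` short fragments.  Each
tree is a branching random walk whose segments follow the 8 compass
directions, which keeps raster lengths exact (axial step = pixel_size,
diagonal step = sqrt(2) * pixel_size) and lets the skeletonization stage thin
the rendered filament back onto the generating polyline.

Trees are confined to disjoint blocks of a shuffled grid partition of the
field with a safety margin, so distinct ground-truth trees can never merge in
the rendering and the detected tree count is comparable to the truth.

Rendering follows the standard fluorescence model: the polyline raster is
dilated to a ~3 px filament, Gaussian-blurred (sigma = 1 px), scaled to
photon counts, and corrupted by Poisson shot noise plus Gaussian read noise
(both optional, off at ``apply_noise=False``).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology as skmorph

from photoskin.images import RasterImage

_SQRT2 = math.sqrt(2.0)
_DIRECTIONS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclasses.dataclass(frozen=True)
class MitoTruth:
    """Ground truth for one synthetic cell.

    ``trees`` is a list of trees; each tree is a list of branch polylines
    with vertex coordinates in micrometres (row, col).
    """

    trees: list[list[np.ndarray]]
    fragmentation: float
    pixel_size: float
    shape: tuple[int, int]
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def branch_length(self, polyline: np.ndarray) -> float:
        deltas = np.diff(polyline, axis=0)
        return float(np.hypot(deltas[:, 0], deltas[:, 1]).sum())

    def tree_lengths(self) -> list[float]:
        return [sum(self.branch_length(b) for b in tree) for tree in self.trees]

    @property
    def total_length(self) -> float:
        return float(sum(self.tree_lengths()))

    def metrics(self) -> dict[str, float]:
        """Truth-side analogues of the per-cell network metrics."""
        lengths = self.tree_lengths()
        total = sum(lengths)
        n_trees = len(lengths)
        n_branches = sum(len(tree) for tree in self.trees)
        return {
            "network_total_length": total,
            "n_trees": n_trees,
            "trees_per_length": n_trees / total if total else float("nan"),
            "avg_tree_length": total / n_trees if n_trees else float("nan"),
            "n_branches": n_branches,
            "branches_per_length": n_branches / total if total else float("nan"),
        }


#: Chebyshev clearance (px) kept between distinct filament center lines so the
#: rendered (dilated + blurred) filaments never merge and the skeleton traces
#: each polyline separately.
_CLEARANCE = 4


def _mark(occupied: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> None:
    h, w = occupied.shape
    for r, c in zip(rr, cc):
        occupied[max(r - _CLEARANCE, 0) : r + _CLEARANCE + 1, max(c - _CLEARANCE, 0) : c + _CLEARANCE + 1] = True


def _walk_tree(
    rng: np.random.Generator,
    block: tuple[int, int, int, int],
    budget_um: float,
    pixel_size: float,
    p_side_branch: float,
    occupied: np.ndarray,
) -> list[list[tuple[int, int]]]:
    """Branching self-avoiding compass walk inside ``block`` (r0, r1, c0, c1).

    Returns a list of branch polylines (pixel-coordinate vertex lists).  The
    walk consumes the length budget segment by segment; side branches restart
    from a previously visited vertex.  Segments reject pixels closer than the
    clearance to already-drawn filament (the first few pixels after an anchor
    are exempt, since they necessarily sit next to the parent line).
    """
    from skimage import draw as skdraw

    r0, r1, c0, c1 = block
    start = (int(rng.integers(r0, r1)), int(rng.integers(c0, c1)))
    polylines: list[list[tuple[int, int]]] = [[start]]
    anchors: list[tuple[int, int]] = [start]
    remaining = budget_um
    attempts = 0
    failures = 0
    while remaining > pixel_size * 0.999 and attempts < 3000:
        attempts += 1
        if (len(polylines[-1]) > 1 and rng.random() < p_side_branch) or failures >= 8:
            anchor = anchors[int(rng.integers(len(anchors)))]
            polylines.append([anchor])
            failures = 0
        line = polylines[-1]
        cur = line[-1]
        d = _DIRECTIONS[int(rng.integers(8))]
        step_cost = pixel_size * (_SQRT2 if d[0] and d[1] else 1.0)
        max_by_budget = int(remaining // step_cost)
        if max_by_budget == 0:
            failures += 1
            continue
        if d[0] > 0:
            room_r = r1 - 1 - cur[0]
        elif d[0] < 0:
            room_r = cur[0] - r0
        else:
            room_r = 10**9
        if d[1] > 0:
            room_c = c1 - 1 - cur[1]
        elif d[1] < 0:
            room_c = cur[1] - c0
        else:
            room_c = 10**9
        n_steps = min(int(rng.integers(12, 28)), max_by_budget, min(room_r, room_c))
        if n_steps <= 0:
            failures += 1
            continue
        nxt = (cur[0] + d[0] * n_steps, cur[1] + d[1] * n_steps)
        rr, cc = skdraw.line(cur[0], cur[1], nxt[0], nxt[1])
        exempt = _CLEARANCE + 1
        if occupied[rr[exempt:], cc[exempt:]].any():
            failures += 1
            continue
        _mark(occupied, rr, cc)
        line.append(nxt)
        anchors.append(nxt)
        remaining -= n_steps * step_cost
        failures = 0
    return [line for line in polylines if len(line) > 1]


def gen_mito_image(
    *,
    fragmentation: float,
    seed: int,
    total_length: float = 450.0,
    pixel_size: float = 0.3,
    shape: tuple[int, int] = (320, 320),
    n_trees_max: int = 30,
    p_side_branch: float = 0.10,
    filament_intensity: float = 600.0,
    background: float = 20.0,
    read_noise: float = 3.0,
    apply_noise: bool = True,
) -> tuple[RasterImage, MitoTruth]:
    """Render one synthetic cell and return the image with its ground truth.

    Parameters
    ----------
    fragmentation:
        Stress level in [0, 1]; 0 gives a single connected network, 1 gives
        ``n_trees_max`` fragments sharing the same total length budget.
    total_length:
        Network total length budget in micrometres (um); the default matches
        the scale of an unstressed fibroblast network (~450 um).
    pixel_size:
        um per pixel; the 0.3 default corresponds to a 40x high-content
        objective.
    """
    if not 0.0 <= fragmentation <= 1.0:
        raise ValueError("fragmentation must lie in [0, 1]")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if min(shape) < 32:
        raise ValueError("image dimensions too small to contain any filament")

    rng = np.random.default_rng(seed)
    n_trees = max(1, round(1 + fragmentation * (n_trees_max - 1)))
    grid = math.ceil(math.sqrt(n_trees))
    block_h, block_w = shape[0] // grid, shape[1] // grid
    margin = 3
    if block_h - 2 * margin < 4 or block_w - 2 * margin < 4:
        raise ValueError("image dimensions too small for the requested fragmentation")

    block_ids = rng.permutation(grid * grid)[:n_trees]
    budget = total_length / n_trees
    trees_um: list[list[np.ndarray]] = []
    canvas = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)
    for bid in block_ids:
        br, bc = divmod(int(bid), grid)
        block = (
            br * block_h + margin,
            (br + 1) * block_h - margin,
            bc * block_w + margin,
            (bc + 1) * block_w - margin,
        )
        polylines = _walk_tree(rng, block, budget, pixel_size, p_side_branch, occupied)
        if not polylines:  # degenerate budget; drop a single 2-px stub
            r = int(rng.integers(block[0], block[1] - 1))
            c = int(rng.integers(block[2], block[3]))
            polylines = [[(r, c), (r + 1, c)]]
        for line in polylines:
            for (r_a, c_a), (r_b, c_b) in zip(line, line[1:]):
                rr, cc = skdraw.line(r_a, c_a, r_b, c_b)
                canvas[rr, cc] = True
        trees_um.append([np.asarray(line, dtype=float) * pixel_size for line in polylines])

    filament = skmorph.dilation(canvas, skmorph.disk(1))
    blurred = ndi.gaussian_filter(filament.astype(float), 1.0)
    photons = background + filament_intensity * blurred
    if apply_noise:
        photons = rng.poisson(photons).astype(float)
        photons += rng.normal(0.0, read_noise, size=photons.shape)
    pixels = np.clip(photons, 0, 65535).astype(np.uint16)

    truth = MitoTruth(
        trees=trees_um,
        fragmentation=fragmentation,
        pixel_size=pixel_size,
        shape=shape,
        seed=seed,
    )
    return RasterImage(pixels=pixels, pixel_size=pixel_size), truth
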