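"""Small hand-drawn skeleton rasters (all <= 15x15) used as graph fixtures."""

from __future__ import annotations

import numpy as np


def axial_line(n: int = 11) -> np.ndarray:
    a = np.zeros((3, n + 2), dtype=bool)
    a[1, 1 : n + 1] = True
    return a


def diagonal_line(n: int = 8) -> np.ndarray:
    a = np.zeros((n + 2, n + 2), dtype=bool)
    for i in range(n):
        a[1 + i, 1 + i] = True
    return a


def t_shape() -> np.ndarray:
    """Horizontal 5-px bar; vertical 7-px stem from the bar's center."""
    a = np.zeros((11, 11), dtype=bool)
    a[2, 3:8] = True
    a[2:9, 5] = True
    return a


def y_shape() -> np.ndarray:
    """Two diagonal arms meeting a vertical stem."""
    a = np.zeros((11, 11), dtype=bool)
    for i in range(4):
        a[1 + i, 1 + i] = True  # upper-left arm
        a[1 + i, 9 - i] = True  # upper-right arm
    a[5:10, 5] = True  # stem
    a[4, 4] = a[4, 6] = False
    a[4, 5] = True  # meeting pixel
    return a


def plus_shape() -> np.ndarray:
    a = np.zeros((9, 9), dtype=bool)
    a[4, 1:8] = True
    a[1:8, 4] = True
    return a


def diamond_ring(radius: int = 3) -> np.ndarray:
    """Node-free closed loop: |r - c0| + |c - c0| == radius."""
    size = 2 * radius + 3
    a = np.zeros((size, size), dtype=bool)
    c0 = radius + 1
    for r in range(size):
        for c in range(size):
            if abs(r - c0) + abs(c - c0) == radius:
                a[r, c] = True
    return a


def two_components() -> np.ndarray:
    a = np.zeros((11, 15), dtype=bool)
    a[2, 1:7] = True
    for i in range(5):
        a[8 - i, 9 + i] = True
    return a


def isolated_pixel() -> np.ndarray:
    a = np.zeros((5, 5), dtype=bool)
    a[2, 2] = True
    return a


def pixel_pair() -> np.ndarray:
    a = np.zeros((5, 5), dtype=bool)
    a[2, 2] = a[3, 3] = True
    return a


FIXTURES = {
    "axial_line": axial_line(),
    "diagonal_line": diagonal_line(),
    "t_shape": t_shape(),
    "y_shape": y_shape(),
    "plus_shape": plus_shape(),
    "diamond_ring": diamond_ring(),
    "two_components": two_components(),
    "isolated_pixel": isolated_pixel(),
    "pixel_pair": pixel_pair(),
}
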