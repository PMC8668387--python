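"""Shared raster-building helpers for the test suite.

All fixtures build tiny binary images programmatically; nothing is loaded
from disk.
"""

import numpy as np
import pytest
from skimage.draw import line as draw_line


def draw_thick_line(canvas, r0, c0, r1, c1, width=1):
    """Stamp a straight stroke of the given width onto a canvas (in place)."""
    rr, cc = draw_line(r0, c0, r1, c1)
    half = (width - 1) // 2
    for dr in range(-half, width - half):
        for dc in range(-half, width - half):
            r = np.clip(rr + dr, 0, canvas.shape[0] - 1)
            c = np.clip(cc + dc, 0, canvas.shape[1] - 1)
            canvas[r, c] = 1
    return canvas


@pytest.fixture
def y_junction():
    """Three 1-px arms of ~25 px meeting at the center of a 64x64 canvas."""
    arr = np.zeros((64, 64), dtype=np.uint8)
    center = (32, 32)
    for angle in (90, 210, 330):
        t = np.radians(angle)
        end = (int(round(32 + 25 * np.sin(t))), int(round(32 + 25 * np.cos(t))))
        rr, cc = draw_line(center[0], center[1], end[0], end[1])
        arr[rr, cc] = 1
    return arr


@pytest.fixture
def plus_cross():
    """Two 5-px-wide bars crossing at right angles."""
    arr = np.zeros((64, 64), dtype=np.uint8)
    arr[30:35, 5:60] = 1
    arr[5:60, 30:35] = 1
    return arr


def brute_force_neighbor_counts(skeleton):
    """Independent 8-neighbor counter (no convolution)."""
    sk = skeleton.astype(bool)
    counts = np.zeros(sk.shape, dtype=int)
    h, w = sk.shape
    for r in range(h):
        for c in range(w):
            if not sk[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and sk[rr, cc]:
                        n += 1
            counts[r, c] = n
    return counts


def sierpinski_carpet(depth):
    """Closed-form fractal with Hausdorff dimension log 8 / log 3."""
    a = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        a = np.block([[a, a, a], [a, np.zeros_like(a), a], [a, a, a]])
    return a.astype(np.uint8)
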