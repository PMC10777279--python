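"""Polygon rasterization.

Polygons are closed vertex loops in continuous ``(row, col)`` coordinates
where pixel ``(r, c)`` occupies the unit square ``[r, r+1) x [c, c+1)``.
A pixel belongs to a polygon when its center ``(r + 0.5, c + 0.5)`` lies
inside under the even-odd rule; overlapping polygons union. This fixed
rule keeps rasterized areas reproducible across platforms, which matters
because every agreement metric downstream is a pixel count.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def points_in_polygon(points: np.ndarray, loop: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test.

    Parameters
    ----------
    points : (m, 2) array of (row, col) query points.
    loop : (n, 2) array of polygon vertices; the loop closes implicitly.
    """
    points = np.asarray(points, dtype=float)
    loop = np.asarray(loop, dtype=float)
    if loop.ndim != 2 or loop.shape[1] != 2 or len(loop) < 3:
        raise ValueError("polygon loop must be an (n>=3, 2) array")
    y, x = points[:, 0], points[:, 1]
    vy, vx = loop[:, 0], loop[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(loop)
    for i in range(n):
        j = (i + 1) % n
        crosses = (vy[i] > y) != (vy[j] > y)
        if not crosses.any():
            continue
        # col coordinate where the edge crosses the horizontal line at y
        t = (y - vy[i]) / (vy[j] - vy[i])
        xint = vx[i] + t * (vx[j] - vx[i])
        inside ^= crosses & (x < xint)
    return inside


def rasterize_polygons(polygons: Sequence[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Union of polygon interiors sampled at pixel centers.

    An empty polygon list yields an all-false mask. Degenerate loops
    (< 3 vertices) are rejected.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    for loop in polygons:
        loop = np.asarray(loop, dtype=float)
        if loop.ndim != 2 or loop.shape[1] != 2 or len(loop) < 3:
            raise ValueError("polygon loop must be an (n>=3, 2) array")
        # restrict the test to the loop's bounding box
        r0 = max(int(np.floor(loop[:, 0].min() - 0.5)), 0)
        r1 = min(int(np.ceil(loop[:, 0].max() + 0.5)), h)
        c0 = max(int(np.floor(loop[:, 1].min() - 0.5)), 0)
        c1 = min(int(np.ceil(loop[:, 1].max() + 0.5)), w)
        if r1 <= r0 or c1 <= c0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        centers = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
        hit = points_in_polygon(centers, loop).reshape(r1 - r0, c1 - c0)
        mask[r0:r1, c0:c1] |= hit
    return mask
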