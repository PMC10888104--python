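"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration, staying off the
code paths it is used to check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_force_three_class_otsu(gray: np.ndarray) -> tuple[int, int, float]:
    """Exhaustive tri-level Otsu: loop over all (t1, t2) pairs.

    Returns (t1, t2, best between-class variance); ties resolved toward
    the smallest pair, matching the documented convention.
    """
    g = np.asarray(gray).ravel().astype(float)
    mu = g.mean()
    best = (-1, -1, -np.inf)
    for t1 in range(256):
        for t2 in range(t1 + 1, 256):
            var_b = 0.0
            for lo, hi in ((-1, t1), (t1, t2), (t2, 255)):
                sel = (g > lo) & (g <= hi)
                w = sel.mean()
                if w > 0:
                    var_b += w * (g[sel].mean() - mu) ** 2
            if var_b > best[2] + 1e-12:
                best = (t1, t2, var_b)
    return best


def bfs_largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component via flood fill; ties broken toward the
    component whose first pixel comes earliest in row-major order."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    best_pixels: list[tuple[int, int]] = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                pixels = []
                queue = deque([(r0, c0)])
                seen[r0, c0] = True
                while queue:
                    r, c = queue.popleft()
                    pixels.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h and 0 <= cc < w
                                and mask[rr, cc] and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                if len(pixels) > len(best_pixels):
                    best_pixels = pixels  # first-found wins ties
    out = np.zeros_like(mask)
    for r, c in best_pixels:
        out[r, c] = True
    return out


def fill_holes_by_complement(mask: np.ndarray) -> np.ndarray:
    """Hole filling via complement flood fill from the border (4-connected
    background, matching the duality of 8-connected foreground)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    outside = np.zeros_like(mask)
    queue = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                queue.append((rr, cc))
    return mask | ~outside


def column_rule_oracle(
    col_pixels: np.ndarray, surface_row: float, pixel_scale: float
) -> tuple[float, float] | None:
    """Depth/width of one column by direct pixel counting: width = number
    of set pixels, centre = midpoint of the extreme boundary coordinates."""
    rows = np.flatnonzero(np.asarray(col_pixels, dtype=bool))
    if rows.size == 0:
        return None
    center = (rows.min() + rows.max() + 1) / 2.0  # exclusive upper boundary
    depth = (center - surface_row) * pixel_scale
    width = rows.size * pixel_scale
    return depth, width
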