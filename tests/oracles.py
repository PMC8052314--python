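"""Independent brute-force oracles used to cross-check the fast metric code.

Everything here works by painting boxes onto an integer pixel grid and
counting pixels, or by exhaustive enumeration — deliberately slow and
obviously correct, never sharing code with the implementation under test.
"""

from __future__ import annotations

import numpy as np

from ampulla.geometry import BBox


def paint(box: BBox, grid_w: int, grid_h: int) -> np.ndarray:
    """Rasterize an integer box onto a boolean grid (half-open convention)."""
    a = np.zeros((grid_h, grid_w), dtype=bool)
    a[int(box.y) : int(box.y + box.h), int(box.x) : int(box.x + box.w)] = True
    return a


def pixel_iou(a: BBox, b: BBox, grid_w: int, grid_h: int) -> float:
    ga, gb = paint(a, grid_w, grid_h), paint(b, grid_w, grid_h)
    union = np.logical_or(ga, gb).sum()
    return np.logical_and(ga, gb).sum() / union


def pixel_precision_recall(pred: BBox, gt: BBox, grid_w: int, grid_h: int) -> tuple[float, float]:
    gp, gg = paint(pred, grid_w, grid_h), paint(gt, grid_w, grid_h)
    inter = np.logical_and(gp, gg).sum()
    return inter / gp.sum(), inter / gg.sum()


def pixel_centroid(box: BBox, grid_w: int, grid_h: int) -> tuple[float, float]:
    """Centroid of the painted pixels (pixel centers at half-integers)."""
    g = paint(box, grid_w, grid_h)
    rows, cols = np.nonzero(g)
    return cols.mean() + 0.5, rows.mean() + 0.5


def pixel_centroid_distance(gt: BBox, est: BBox, grid_w: int, grid_h: int) -> float:
    xg, yg = pixel_centroid(gt, grid_w, grid_h)
    xe, ye = pixel_centroid(est, grid_w, grid_h)
    return 0.5 * (abs(xg - xe) / grid_w + abs(yg - ye) / grid_h)


def brute_force_peak_component_box(mask: np.ndarray, threshold: float) -> tuple[int, int, int, int]:
    """Flood-fill from the peak over 8-connected pixels above the threshold
    of the peak-normalized mask; returns (x, y, w, h) of the tight box."""
    norm = mask / mask.max()
    keep = norm > threshold
    peak = np.unravel_index(int(np.argmax(norm)), norm.shape)
    keep[peak] = True
    seen = np.zeros_like(keep)
    stack = [peak]
    seen[peak] = True
    h, w = mask.shape
    while stack:
        i, j = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and keep[ni, nj] and not seen[ni, nj]:
                    seen[ni, nj] = True
                    stack.append((ni, nj))
    rows, cols = np.nonzero(seen)
    return int(cols.min()), int(rows.min()), int(cols.max() - cols.min() + 1), int(rows.max() - rows.min() + 1)


def random_integer_box(rng: np.random.Generator, grid: int) -> BBox:
    w = int(rng.integers(1, grid // 2))
    h = int(rng.integers(1, grid // 2))
    x = int(rng.integers(0, grid - w))
    y = int(rng.integers(0, grid - h))
    return BBox(x, y, w, h)


def random_area_fraction_box(
    rng: np.random.Generator, size: int, min_frac: float = 0.05, max_frac: float = 0.5,
    aspect_lo: float = 0.5, aspect_hi: float = 2.0,
) -> BBox:
    """Random real-valued box covering min_frac..max_frac of the image area."""
    for _ in range(1000):
        frac = rng.uniform(min_frac, max_frac)
        aspect = rng.uniform(aspect_lo, aspect_hi)
        area = frac * size * size
        w = np.sqrt(area * aspect)
        h = area / w
        if w >= size or h >= size:
            continue
        x = rng.uniform(0, size - w)
        y = rng.uniform(0, size - h)
        return BBox(x, y, w, h)
    raise RuntimeError("could not sample a box")
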