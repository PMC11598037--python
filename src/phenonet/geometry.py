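"""Polygon/mask geometry helpers.

Conventions: 0-based pixel coordinates; vertex (x, y) addresses the centre of
pixel column x, row y.  Rasterisation uses the centre-in-polygon rule, so the
mask of a flipped polygon is exactly the flipped mask.  Boxes are half-open
[x0, x1) x [y0, y1) in pixel units.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path
from scipy.spatial import ConvexHull


def rasterize_polygon(polygon: np.ndarray, height: int, width: int) -> np.ndarray:
    """Binary mask of pixels whose centres fall inside the polygon."""
    poly = np.asarray(polygon, dtype=np.float64)
    path = Path(poly)
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())) + 1, width)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())) + 1, height)
    mask = np.zeros((height, width), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    # tiny positive radius makes boundary handling symmetric under flips
    inside = path.contains_points(pts, radius=1e-9)
    mask[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    return mask


def polygon_bbox(polygon: np.ndarray) -> np.ndarray:
    """Half-open (x0, y0, x1, y1) box enclosing the polygon's pixel footprint."""
    poly = np.asarray(polygon, dtype=np.float64)
    return np.array([poly[:, 0].min(), poly[:, 1].min(),
                     poly[:, 0].max() + 1.0, poly[:, 1].max() + 1.0])


def mask_bbox(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask has no bbox")
    return np.array([xs.min(), ys.min(), xs.max() + 1.0, ys.max() + 1.0],
                    dtype=np.float64)


def max_caliper_extent_px(mask: np.ndarray) -> float:
    """Largest pairwise distance between pixel centres of a binary mask.

    Uses the convex hull: the diameter of a point set is attained on hull
    vertices, so the exhaustive pairwise search runs on the hull only.
    """
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return 0.0
    pts = np.column_stack([xs, ys]).astype(np.float64)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) sets fall back to all points
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between two (N,4) / (M,4) arrays of half-open boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.5) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores)
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        ious = box_iou(boxes[i], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return np.array(keep, dtype=int)
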