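"""Circular-cell detection by circular Hough transform with radius tolerance.

Cells of a population are located frame by frame as circular objects within a
configured radius range; distinct populations (e.g. large cancer cells vs
immune cells roughly a third of their radius) are separated simply by running
the detector with disjoint radius ranges. The edge map is a thresholded
gradient magnitude; accumulator peaks are reduced by greedy non-maximum
suppression and refined to sub-pixel centers by a 3x3 accumulator centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import sobel, threshold_otsu
from skimage.transform import hough_circle

__all__ = ["Detection", "detect_cells", "detect_video"]


@dataclass(frozen=True)
class Detection:
    frame: int
    x: float
    y: float
    r: float
    score: float


def _edge_map(image: np.ndarray) -> np.ndarray:
    grad = sobel(image.astype(float))
    if grad.max() <= 0:
        return np.zeros_like(grad, dtype=bool)
    try:
        thr = threshold_otsu(grad)
    except ValueError:  # constant gradient image
        return np.zeros_like(grad, dtype=bool)
    return grad > thr


def detect_cells(
    frame_image: np.ndarray,
    radius_range: tuple[int, int],
    sensitivity: float = 0.5,
    frame: int = 0,
) -> list[Detection]:
    """Detect circular cells in one grayscale frame.

    ``sensitivity`` is a normalized accumulator threshold in (0, 1]: a full,
    clean circle scores ~1. Detections are returned sorted by descending
    score; no two detections lie within ``r_min`` of each other; radii are
    within ``radius_range``. A blank or degenerate frame yields an empty list.
    """
    r_min, r_max = int(radius_range[0]), int(radius_range[1])
    if not (1 <= r_min <= r_max):
        raise ValueError("radius_range must satisfy 1 <= r_min <= r_max")
    if not (0 < sensitivity <= 1):
        raise ValueError("sensitivity must be in (0, 1]")
    image = np.asarray(frame_image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D grayscale frame")
    edges = _edge_map(image)
    if not edges.any():
        return []
    radii = np.arange(r_min, r_max + 1)
    acc = hough_circle(edges, radii, normalize=True)  # (n_radii, H, W)

    # collect candidate peaks above the sensitivity threshold, all radii pooled
    from skimage.feature import peak_local_max

    candidates = []
    for k, r in enumerate(radii):
        for py, px in peak_local_max(
            acc[k], min_distance=max(1, r_min // 2), threshold_abs=sensitivity
        ):
            candidates.append((float(acc[k, py, px]), int(px), int(py), int(r), k))
    candidates.sort(key=lambda c: (-c[0], c[2], c[1], c[3]))

    detections: list[Detection] = []
    kept: list[tuple[int, int]] = []
    for score, px, py, r, k in candidates:  # greedy NMS, discard within r_min of kept
        if any((px - qx) ** 2 + (py - qy) ** 2 < r_min**2 for qx, qy in kept):
            continue
        kept.append((px, py))
        # sub-pixel refinement: centroid of the 3x3 accumulator neighborhood
        y0, y1 = max(py - 1, 0), min(py + 2, acc.shape[1])
        x0, x1 = max(px - 1, 0), min(px + 2, acc.shape[2])
        patch = acc[k, y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        w = patch.sum()
        cx = float((patch * xx).sum() / w) if w > 0 else float(px)
        cy = float((patch * yy).sum() / w) if w > 0 else float(py)
        detections.append(Detection(frame, cx, cy, float(r), float(score)))
    return detections


def detect_video(
    stack: np.ndarray,
    radius_range: tuple[int, int],
    sensitivity: float = 0.5,
    video_id: str = "",
) -> pd.DataFrame:
    """Run the detector on every frame of a stack; returns the detections table."""
    rows = []
    for f, frame_image in enumerate(stack):
        for d in detect_cells(frame_image, radius_range, sensitivity, frame=f):
            rows.append((video_id, d.frame, d.x, d.y, d.r, d.score))
    return pd.DataFrame(rows, columns=["video_id", "frame", "x", "y", "r", "score"])
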