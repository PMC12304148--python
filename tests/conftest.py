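"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
expansion is re-derived by exhaustive per-pixel distance comparison,
region statistics by explicit python loops.
"""

from __future__ import annotations

import numpy as np
import pytest

from cytoquant.segmentation import LabelMap


def brute_force_footprints(
    label_arr: np.ndarray, radius_px: float, mode: str
) -> dict[int, np.ndarray]:
    """Exhaustive per-pixel Euclidean-distance expansion oracle.

    Enumerates every (pixel, label-pixel) pair via cdist — no distance
    transform involved. independent: pixel p belongs to label L's
    footprint iff min over L's pixels q of dist(p, q) <= radius_px.
    exclusive: p goes only to the label with the smallest such distance
    (ties to the smaller label id); nucleus pixels stay with their label.
    """
    from scipy.spatial.distance import cdist

    h, w = label_arr.shape
    ids = sorted(int(v) for v in np.unique(label_arr) if v > 0)
    grid = np.argwhere(np.ones((h, w), dtype=bool)).astype(float)
    min_dist = {}
    for lid in ids:
        pts = np.argwhere(label_arr == lid).astype(float)
        d = cdist(grid, pts).min(axis=1).reshape(h, w)
        min_dist[lid] = d
    if mode == "independent":
        return {lid: min_dist[lid] <= radius_px for lid in ids}
    best_d = np.full((h, w), np.inf)
    best_lid = np.zeros((h, w), dtype=int)
    for lid in ids:  # ascending: strict < keeps the smaller id on ties
        better = min_dist[lid] < best_d
        best_d[better] = min_dist[lid][better]
        best_lid[better] = lid
    return {lid: (best_lid == lid) & (best_d <= radius_px) for lid in ids}


def brute_force_region_stats(channel_plane: np.ndarray, mask: np.ndarray) -> dict:
    """Loop-based statistics over a region for checking measure_cells."""
    vals = [float(channel_plane[y, x]) for y, x in np.argwhere(mask)]
    if not vals:
        return {"area": 0}
    return {
        "area": len(vals),
        "mean": sum(vals) / len(vals),
        "sum": sum(vals),
        "min": min(vals),
        "max": max(vals),
    }


def random_label_map(rng: np.random.Generator, size: int = 32, max_labels: int = 5) -> LabelMap:
    """Sparse random blobs: a few seed pixels grown by random strokes."""
    arr = np.zeros((size, size), dtype=np.int32)
    n = rng.integers(1, max_labels + 1)
    for lid in range(1, n + 1):
        cy, cx = rng.integers(0, size, 2)
        arr[cy, cx] = lid
        for _ in range(int(rng.integers(1, 12))):
            cy = int(np.clip(cy + rng.integers(-1, 2), 0, size - 1))
            cx = int(np.clip(cx + rng.integers(-1, 2), 0, size - 1))
            if arr[cy, cx] == 0:
                arr[cy, cx] = lid
    return LabelMap.from_array(arr, pixel_size_um=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
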