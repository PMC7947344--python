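"""Independent brute-force oracles used to verify the production pipeline.

Everything here is deliberately naive — O(n²) pairwise scans over boundary
pixels or channel positions — and shares no code with the production paths
(which use windowed Euclidean distance transforms).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

EIGHT = np.ones((3, 3), dtype=bool)


def boundary_pixels(labels: np.ndarray, lab: int) -> np.ndarray:
    """(K, 2) row/col coordinates of the cluster's boundary pixels."""
    cluster = labels == lab
    interior = ndimage.binary_erosion(cluster, structure=EIGHT, border_value=0)
    rows, cols = np.nonzero(cluster & ~interior)
    return np.column_stack([rows, cols]).astype(float)


def brute_force_nnd(labels: np.ndarray) -> dict[int, float]:
    """Min pixel-centre distance from each cluster to any other, by pairwise scan."""
    labs = [int(v) for v in np.unique(labels) if v > 0]
    bounds = {lab: boundary_pixels(labels, lab) for lab in labs}
    out: dict[int, float] = {}
    for a in labs:
        best = np.inf
        for b in labs:
            if a == b:
                continue
            best = min(best, cdist(bounds[a], bounds[b]).min())
        out[a] = best
    return out


def brute_force_pair_distances(labels: np.ndarray) -> dict[tuple[int, int], float]:
    """All pairwise min boundary-pixel distances (i < j, 1-based labels)."""
    labs = [int(v) for v in np.unique(labels) if v > 0]
    bounds = {lab: boundary_pixels(labels, lab) for lab in labs}
    out = {}
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            out[(a, b)] = float(cdist(bounds[a], bounds[b]).min())
    return out


def brute_force_partition(labels: np.ndarray, cutoff_px: float) -> dict[int, int]:
    """Union-find grouping of clusters with pairwise distance <= cutoff."""
    labs = [int(v) for v in np.unique(labels) if v > 0]
    parent = {lab: lab for lab in labs}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), d in brute_force_pair_distances(labels).items():
        if d <= cutoff_px:
            parent[find(a)] = find(b)
    return {lab: find(lab) for lab in labs}


def canonical_partition(mapping: dict[int, int]) -> frozenset[frozenset[int]]:
    groups: dict[int, set[int]] = {}
    for member, root in mapping.items():
        groups.setdefault(root, set()).add(member)
    return frozenset(frozenset(g) for g in groups.values())


def random_blob_mask(rng: np.random.Generator, size: int = 256,
                     n_blobs: int | None = None) -> np.ndarray:
    """Random labelled mask of rectangles and disks (>= 2 clusters)."""
    if n_blobs is None:
        n_blobs = int(rng.integers(3, 12))
    while True:
        mask = np.zeros((size, size), dtype=bool)
        for _ in range(n_blobs):
            r = int(rng.integers(5, size - 5))
            c = int(rng.integers(5, size - 5))
            if rng.random() < 0.5:
                hh, ww = int(rng.integers(1, 12)), int(rng.integers(1, 12))
                mask[max(0, r - hh):r + hh + 1, max(0, c - ww):c + ww + 1] = True
            else:
                rad = float(rng.uniform(1, 8))
                rr, cc = np.ogrid[:size, :size]
                mask |= (rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2
        labels, n = ndimage.label(mask, structure=EIGHT)
        if n >= 2:
            return labels


def true_edge_distance(channels_a: np.ndarray, channels_b: np.ndarray,
                       footprint: float) -> float:
    """Ground-truth edge gap between two clusters of channel centres."""
    return max(0.0, float(cdist(channels_a, channels_b).min()) - footprint)
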