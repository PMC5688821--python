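"""Geometric primitives: oriented bounding boxes, set diameter, clustering.

The oriented bounding box follows the covariance construction used for
fruit sizing: the major axis is the leading eigenvector of the point
covariance matrix, the second axis is the direction of the farthest point
pair after projecting onto the plane orthogonal to the major axis, and the
third axis completes the right-handed frame. This is *not* the
minimum-volume box; it is the data-driven frame that makes the vertical
(holder) axis the major axis when the holder is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree


class DegenerateGeometryError(ValueError):
    """Input points are too few, collinear, or coplanar for the operation."""


@dataclass
class OrientedBBox:
    center: np.ndarray           # (3,)
    axes: np.ndarray             # (3, 3) rows = major, second, third (unit)
    extents: np.ndarray          # (3,) lengths along the rows of `axes`

    def contains(self, points: np.ndarray, slack: float = 1e-6) -> np.ndarray:
        local = (np.asarray(points) - self.center) @ self.axes.T
        half = self.extents / 2 + slack
        return np.all(np.abs(local) <= half, axis=1)

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))


@dataclass
class ClusterSet:
    """Per-point labels (noise = -1) and the count of kept clusters."""

    labels: np.ndarray
    n_clusters: int


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude component is positive (deterministic)."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def fit_obb(points: np.ndarray) -> OrientedBBox:
    """Fit the covariance-major-axis oriented bounding box.

    Raises :class:`DegenerateGeometryError` for < 4 points or (nearly)
    coplanar input. Extents are max-min of projections along each axis; no
    outlier trimming is applied.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points to fit a box")
    centred = pts - pts.mean(axis=0)
    # 1/n covariance; scale does not affect eigenvectors
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    span = np.linalg.norm(centred, axis=0).max()
    if span == 0 or evals[2] <= 0 or evals[1] <= 1e-12 * evals[2]:
        raise DegenerateGeometryError("points are collinear or coincident")
    if evals[0] <= 1e-12 * evals[2]:
        raise DegenerateGeometryError("points are coplanar")
    order = np.argsort(evals)[::-1]
    if np.isclose(evals[order[0]], evals[order[1]], rtol=1e-12, atol=0.0):
        # eigen-tie: deterministic lexicographic break
        pair = sorted(
            (tuple(_canonical_sign(evecs[:, order[k]])), order[k]) for k in (0, 1)
        )
        order[0], order[1] = pair[1][1], pair[0][1]
    major = _canonical_sign(evecs[:, order[0]])

    # project onto the plane orthogonal to the major axis and take the
    # farthest pair there (over 2-D hull vertices: exact and fast)
    proj3 = centred - np.outer(centred @ major, major)
    u = evecs[:, order[1]]
    u = u - (u @ major) * major
    u /= np.linalg.norm(u)
    w = np.cross(major, u)
    flat = np.column_stack([proj3 @ u, proj3 @ w])
    _, (i, j) = _diameter_2d(flat)
    second3 = proj3[i] - proj3[j]
    norm = np.linalg.norm(second3)
    if norm == 0:
        raise DegenerateGeometryError("no spread orthogonal to major axis")
    second = _canonical_sign(second3 / norm)
    third = _canonical_sign(np.cross(major, second))

    axes = np.vstack([major, second, third])
    lo = (pts @ axes.T).min(axis=0)
    hi = (pts @ axes.T).max(axis=0)
    center = axes.T @ ((lo + hi) / 2)
    return OrientedBBox(center=center, axes=axes, extents=hi - lo)


def _diameter_2d(points2d: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Exact diameter of a planar point set via hull vertices."""
    try:
        cand = ConvexHull(points2d).vertices
    except QhullError:
        cand = np.arange(len(points2d))  # collinear/tiny sets: brute force
    return _brute_diameter(points2d, cand)


def _brute_diameter(pts: np.ndarray, cand: np.ndarray):
    sub = pts[cand]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    flat = int(np.argmax(d2))
    a, b = divmod(flat, len(cand))
    return float(np.sqrt(d2[a, b])), (int(cand[a]), int(cand[b]))


def max_pairwise_distance(points: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Exact set diameter and the achieving index pair.

    The diameter of a finite set is realised by convex-hull vertices, so the
    O(h^2) scan runs on the hull only; degenerate (flat) inputs fall back to
    the full point set.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 2:
        raise DegenerateGeometryError("need at least 2 points")
    if len(pts) <= 16:
        return _brute_diameter(pts, np.arange(len(pts)))
    try:
        cand = ConvexHull(pts).vertices
    except QhullError:
        cand = np.arange(len(pts))
    return _brute_diameter(pts, cand)


def euclidean_cluster(
    points: np.ndarray, tolerance: float, min_size: int = 1
) -> ClusterSet:
    """Single-linkage connected components with distance cutoff ``tolerance``.

    Two points are joined when their distance is <= tolerance. Components
    smaller than ``min_size`` are noise (label -1) and do not count. Labels
    of kept clusters are contiguous from 0 in order of first occurrence.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        return ClusterSet(labels=np.empty(0, dtype=np.int64), n_clusters=0)
    pairs = cKDTree(pts).query_pairs(r=tolerance, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    counts = np.bincount(comp)
    labels = np.full(n, -1, dtype=np.int64)
    next_id = 0
    seen: dict[int, int] = {}
    for idx in range(n):
        c = comp[idx]
        if counts[c] < min_size:
            continue
        if c not in seen:
            seen[c] = next_id
            next_id += 1
        labels[idx] = seen[c]
    return ClusterSet(labels=labels, n_clusters=next_id)
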