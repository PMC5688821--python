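import numpy as np
import pytest

from fragaria3d.geometry import (
    DegenerateGeometryError,
    euclidean_cluster,
    fit_obb,
    max_pairwise_distance,
)
from conftest import random_rotation


def cuboid_grid(lx=2.0, ly=1.0, lz=0.5, n=12):
    """Dense regular grid filling [0,lx]x[0,ly]x[0,lz]."""
    ax = np.linspace(0, lx, 2 * n + 1)
    ay = np.linspace(0, ly, n + 1)
    az = np.linspace(0, lz, n // 2 + 1)
    g = np.meshgrid(ax, ay, az, indexing="ij")
    return np.column_stack([a.ravel() for a in g])


def brute_clusters(points, tol, min_size):
    """Union-find over the full O(n^2) distance matrix (oracle)."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d2 = np.sum((points[:, None] - points[None, :]) ** 2, axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= tol * tol:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    sizes = {}
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    kept = {r for r, s in sizes.items() if s >= min_size}
    return roots, len(kept)


class TestFitObb:
    def test_axis_aligned_cuboid(self):
        obb = fit_obb(cuboid_grid())
        # major axis is +-x; extent along it is exact
        assert abs(abs(obb.axes[0][0]) - 1) < 1e-9
        assert abs(obb.extents[0] - 2.0) < 1e-9
        # the farthest-pair second axis of a 1 x 0.5 rectangular section is
        # its diagonal: extents sqrt(1.25) and 2*(1*0.5)/sqrt(1.25)
        assert abs(obb.extents[1] - np.sqrt(1.25)) < 1e-9
        assert abs(obb.extents[2] - 1.0 / np.sqrt(1.25)) < 1e-9

    def test_rotated_cuboid_recovers_major_axis_and_extents(self, rng):
        pts = cuboid_grid()
        ref = fit_obb(pts)
        for _ in range(20):
            rot = random_rotation(rng)
            shift = rng.uniform(-10, 10, size=3)
            obb = fit_obb(pts @ rot.T + shift)
            np.testing.assert_allclose(obb.extents, ref.extents, rtol=1e-2)
            # major axis equals R applied to x, up to sign
            assert abs(abs(obb.axes[0] @ rot[:, 0]) - 1) < 1e-6

    def test_containment(self, rng):
        pts = rng.normal(size=(500, 3)) * [3, 2, 1]
        obb = fit_obb(pts)
        assert obb.contains(pts).all()

    def test_axes_orthonormal(self, rng):
        pts = rng.uniform(size=(200, 3)) * [5, 2, 1]
        obb = fit_obb(pts)
        np.testing.assert_allclose(obb.axes @ obb.axes.T, np.eye(3), atol=1e-8)

    def test_holder_shaped_cloud(self, rng):
        """Square-section cuboid: major extent = height, second axis locks
        onto the cross-section diagonal (a property of the farthest-pair
        rule), at any global scale."""
        for scale in (0.36 / 38, 1.0, 1.73 / 38):
            pts = cuboid_grid(38, 19, 19, n=14) * scale
            obb = fit_obb(pts)
            assert abs(obb.extents[0] / scale - 38) < 0.02 * 38
            assert abs(obb.extents[1] / scale - 19 * np.sqrt(2)) < 0.02 * 19
            assert abs(obb.extents[2] / scale - 19 * np.sqrt(2)) < 0.02 * 19

    @pytest.mark.parametrize(
        "pts",
        [
            np.zeros((3, 3)),                                   # too few
            np.column_stack([np.arange(10.0)] * 3),             # collinear
            np.c_[np.random.default_rng(0).uniform(size=(20, 2)), np.zeros(20)],
        ],
    )
    def test_degenerate_inputs_rejected(self, pts):
        with pytest.raises(DegenerateGeometryError):
            fit_obb(pts)

    def test_rigid_motion_invariance_of_extents(self, rng):
        pts = rng.uniform(size=(400, 3)) * [6, 3, 1]
        ref = fit_obb(pts).extents
        for _ in range(10):
            moved = pts @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
            np.testing.assert_allclose(fit_obb(moved).extents, ref, rtol=1e-2)


class TestMaxPairwiseDistance:
    def test_unit_square_diagonal(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        d, (i, j) = max_pairwise_distance(pts)
        assert abs(d - np.sqrt(2)) < 1e-12
        assert {i, j} in ({0, 3}, {1, 2})

    def test_matches_brute_force_on_ball(self, rng):
        pts = rng.normal(size=(500, 3))
        pts /= np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1)
        d, _ = max_pairwise_distance(pts)
        d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=-1)
        assert d == pytest.approx(np.sqrt(d2.max()), abs=0.0)

    def test_coincident_points(self):
        d, _ = max_pairwise_distance(np.zeros((2, 3)))
        assert d == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            max_pairwise_distance(np.zeros((1, 3)))

    def test_returned_pair_realises_distance(self, rng):
        pts = rng.uniform(size=(300, 3))
        d, (i, j) = max_pairwise_distance(pts)
        assert d == pytest.approx(float(np.linalg.norm(pts[i] - pts[j])), abs=0)


class TestEuclideanCluster:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(scale=0.05, size=(10, 3))
        b = a + [5.0, 0, 0]
        cs = euclidean_cluster(np.vstack([a, b]), tolerance=1.0, min_size=1)
        assert cs.n_clusters == 2
        assert (cs.labels[:10] == cs.labels[0]).all()
        assert (cs.labels[10:] == cs.labels[10]).all()
        assert cs.labels[0] != cs.labels[10]

    def test_empty_input(self):
        cs = euclidean_cluster(np.empty((0, 3)), tolerance=1.0)
        assert cs.n_clusters == 0

    def test_min_size_marks_noise(self, rng):
        blob = rng.normal(scale=0.01, size=(8, 3))
        lone = np.array([[10.0, 0, 0]])
        cs = euclidean_cluster(np.vstack([blob, lone]), tolerance=0.5, min_size=3)
        assert cs.n_clusters == 1
        assert cs.labels[-1] == -1

    def test_labels_contiguous_from_zero(self, rng):
        pts = rng.uniform(0, 30, size=(150, 3))
        cs = euclidean_cluster(pts, tolerance=1.5, min_size=2)
        kept = np.unique(cs.labels[cs.labels >= 0])
        np.testing.assert_array_equal(kept, np.arange(cs.n_clusters))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(rng.integers(20, 200), 3))
        tol = float(rng.uniform(0.5, 2.0))
        min_size = int(rng.integers(1, 4))
        cs = euclidean_cluster(pts, tolerance=tol, min_size=min_size)
        roots, n_ref = brute_clusters(pts, tol, min_size)
        assert cs.n_clusters == n_ref
        # identical partitions up to relabelling (noise members excluded)
        ref_parts, got_parts = {}, {}
        for i, r in enumerate(roots):
            ref_parts.setdefault(r, set()).add(i)
        for i, l in enumerate(cs.labels):
            if l >= 0:
                got_parts.setdefault(int(l), set()).add(i)
        ref_kept = {
            frozenset(s) for s in ref_parts.values() if len(s) >= min_size
        }
        assert {frozenset(s) for s in got_parts.values()} == ref_kept

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            euclidean_cluster(np.zeros((3, 3)), tolerance=0.0)
        with pytest.raises(ValueError):
            euclidean_cluster(np.zeros((3, 3)), tolerance=1.0, min_size=0)
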