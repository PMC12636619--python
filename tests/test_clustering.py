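import numpy as np
import pandas as pd
import pytest

from mfsyn import clustering
from mfsyn.clustering import AZEllipse, ClusterParams, NOISE
from mfsyn.errors import ValidationError


def reference_dbscan(points, eps, min_pts):
    """Independent O(n^2) DBSCAN: cores from the full distance matrix,
    clusters as connected components of the core graph, borders attached
    to any adjacent core's cluster."""
    pts = np.asarray(points, float)
    n = len(pts)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    nb = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb[i]) >= min_pts for i in range(n)])
    labels = np.full(n, NOISE)
    cid = 0
    for i in np.flatnonzero(core):
        if labels[i] != NOISE:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in nb[j]:
                if core[k] and labels[k] == NOISE:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    for i in np.flatnonzero(~core):
        adj = [labels[j] for j in nb[i] if core[j]]
        if adj:
            labels[i] = adj[0]  # any adjacent cluster (border tie is free)
    return labels, core


def partitions_agree(labels_a, labels_b, points, eps, core):
    """Partition equality up to renaming; border points may differ only in
    which eps-adjacent cluster claims them."""
    pts = np.asarray(points, float)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    # core points must map one-to-one between labelings
    mapping = {}
    for i in np.flatnonzero(core):
        a, b = labels_a[i], labels_b[i]
        if a in mapping and mapping[a] != b:
            return False
        mapping[a] = b
    for i in np.flatnonzero(~core):
        a, b = labels_a[i], labels_b[i]
        if (a == NOISE) != (b == NOISE):
            return False
        if a == NOISE:
            continue
        # must be adjacent to a core of the claimed cluster in both labelings
        ok_a = any(core[j] and labels_a[j] == a and d[i, j] <= eps for j in range(len(pts)))
        ok_b = any(core[j] and labels_b[j] == b and d[i, j] <= eps for j in range(len(pts)))
        if not (ok_a and ok_b):
            return False
    return True


class TestDbscan:
    def test_fewer_points_than_min_pts_is_all_noise(self, rng):
        pts = rng.normal(0, 5, (4, 3))
        labels = clustering.dbscan(pts, ClusterParams(eps_nm=22.5, min_pts=5))
        assert (labels == NOISE).all()

    def test_min_pts_coincident_points_form_one_cluster(self):
        pts = np.zeros((5, 3))
        labels = clustering.dbscan(pts, ClusterParams(min_pts=5))
        assert (labels == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        # three loose blobs + scatter, 100 points
        pts = np.vstack([
            rng.normal([0, 0, 0], 8, (30, 3)),
            rng.normal([80, 0, 0], 8, (30, 3)),
            rng.normal([0, 90, 0], 8, (20, 3)),
            rng.uniform(-150, 150, (20, 3)),
        ])
        params = ClusterParams(eps_nm=22.5, min_pts=5)
        labels = clustering.dbscan(pts, params)
        ref, core = reference_dbscan(pts, 22.5, 5)
        assert partitions_agree(labels, ref, pts, 22.5, core)

    def test_partition_invariant_under_permutation(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal([0, 0, 0], 8, (25, 3)),
                         rng.normal([100, 0, 0], 8, (25, 3)),
                         rng.uniform(-200, 200, (10, 3))])
        params = ClusterParams(eps_nm=22.5, min_pts=5)
        base = clustering.dbscan(pts, params)
        _, core = reference_dbscan(pts, 22.5, 5)
        for _ in range(10):
            perm = rng.permutation(len(pts))
            lab = clustering.dbscan(pts[perm], params)
            unperm = np.empty_like(lab)
            unperm[perm] = lab
            assert partitions_agree(base, unperm, pts, 22.5, core)

    def test_matches_sklearn_oracle(self):
        sk = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(17)
        pts = np.vstack([rng.normal([0, 0, 0], 8, (40, 3)),
                         rng.normal([120, 50, 0], 8, (40, 3)),
                         rng.uniform(-250, 250, (20, 3))])
        labels = clustering.dbscan(pts, ClusterParams(eps_nm=22.5, min_pts=5))
        skl = sk.DBSCAN(eps=22.5, min_samples=5).fit(pts)
        core = np.zeros(len(pts), bool)
        core[skl.core_sample_indices_] = True
        assert partitions_agree(labels, skl.labels_, pts, 22.5, core)

    def test_every_cluster_contains_a_core_point(self):
        rng = np.random.default_rng(21)
        pts = np.vstack([rng.normal(0, 10, (30, 3)), rng.uniform(-300, 300, (30, 3))])
        labels = clustering.dbscan(pts, ClusterParams(eps_nm=22.5, min_pts=5))
        _, core = reference_dbscan(pts, 22.5, 5)
        for cid in set(labels) - {NOISE}:
            assert core[labels == cid].any()


class TestSummaries:
    def _traces(self, xyz):
        xyz = np.atleast_2d(xyz)
        return pd.DataFrame({"channel": "ch_high_dcr",
                             "x_nm": xyz[:, 0], "y_nm": xyz[:, 1], "z_nm": xyz[:, 2]})

    def test_symmetric_cluster_centroid_at_origin(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 2, 0], [0, -2, 0],
                        [0, 0, 3], [0, 0, -3]], float)
        labels = np.zeros(6, int)
        out = clustering.summarize_clusters(labels, self._traces(pts))
        assert out.loc[0, ["x_nm", "y_nm", "z_nm"]].tolist() == [0, 0, 0]
        assert out.loc[0, "n_members"] == 6

    def test_centroids_equal_brute_force_means(self, rng):
        pts = rng.normal(0, 50, (40, 3))
        labels = rng.integers(-1, 3, 40)
        out = clustering.summarize_clusters(labels, self._traces(pts)).set_index("cluster_id")
        for cid in set(labels) - {NOISE}:
            np.testing.assert_allclose(
                out.loc[cid, ["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float),
                pts[labels == cid].mean(axis=0))

    def test_no_clusters_gives_empty_frame(self):
        out = clustering.summarize_clusters(np.full(5, NOISE), self._traces(np.zeros((5, 3))))
        assert len(out) == 0


class TestAzClassification:
    def _clusters(self, xy):
        xy = np.atleast_2d(xy)
        return pd.DataFrame({"cluster_id": range(len(xy)), "channel": "c",
                             "n_members": 5, "x_nm": xy[:, 0], "y_nm": xy[:, 1],
                             "z_nm": 40.0})

    def test_center_is_inside_for_any_z(self):
        labels, counts = clustering.classify_az(self._clusters([[0.0, 0.0]]))
        assert labels == ["inside"] and counts == {"inside": 1, "periphery": 0}

    def test_boundary_inclusive_and_minor_axis_violation(self):
        labels, _ = clustering.classify_az(self._clusters([[250.0, 0.0], [0.0, 150.0]]))
        assert labels == ["inside", "periphery"]

    def test_counts_match_brute_force_inequality(self, rng):
        xy = rng.uniform(-400, 400, (100, 2))
        labels, counts = clustering.classify_az(self._clusters(xy))
        expected = ((xy[:, 0] / 250) ** 2 + (xy[:, 1] / 100) ** 2) <= 1
        assert counts["inside"] == expected.sum()
        assert [l == "inside" for l in labels] == expected.tolist()

    def test_rotated_ellipse(self):
        ell = AZEllipse(orientation_rad=np.pi / 2)  # major axis along Y
        labels, _ = clustering.classify_az(self._clusters([[0.0, 240.0], [240.0, 0.0]]), ell)
        assert labels == ["inside", "periphery"]


class TestProjection:
    def test_xy_drops_z(self):
        np.testing.assert_array_equal(clustering.project([[1, 2, 3]], "XY"), [[1, 2]])
        np.testing.assert_array_equal(clustering.project([[1, 2, 3]], "XZ"), [[1, 3]])
        np.testing.assert_array_equal(clustering.project([[1, 2, 3]], "YZ"), [[2, 3]])

    def test_preserves_count_and_order(self, rng):
        pts = rng.normal(0, 10, (25, 3))
        out = clustering.project(pts, "XZ")
        assert out.shape == (25, 2)
        np.testing.assert_array_equal(out[:, 0], pts[:, 0])

    def test_invalid_plane_rejected(self):
        with pytest.raises(ValidationError):
            clustering.project([[0, 0, 0]], "XW")
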