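import numpy as np
import pytest

from massdelim.density import (
    BORDER,
    CORE,
    NOISE,
    DensityParams,
    centroid_features,
    dbscan_superpixels,
    extract_mass_mask,
)
from massdelim.superpixels import SuperpixelMap
from oracles import brute_dbscan


def make_spmap(labels: np.ndarray, mu: np.ndarray) -> SuperpixelMap:
    """Build a SuperpixelMap from a label image and a per-pixel mu image
    (nu = 1 - mu, pi = 0)."""
    k = int(labels.max()) + 1
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=k)
    m, n = labels.shape
    rr, cc = np.mgrid[0:m, 0:n]
    rows = np.bincount(flat, weights=rr.ravel(), minlength=k) / sizes
    cols = np.bincount(flat, weights=cc.ravel(), minlength=k) / sizes
    mu_k = np.bincount(flat, weights=mu.ravel(), minlength=k) / sizes
    ifs = np.stack([mu_k, 1.0 - mu_k, np.zeros(k)], axis=1)
    return SuperpixelMap(labels=labels, ifs=ifs, rows=rows, cols=cols, sizes=sizes)


class TestFeatures:
    def setup_method(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:, 5:] = 1
        self.spmap = make_spmap(labels, np.where(labels == 1, 0.8, 0.2))

    def test_ifs_mode_gives_triples(self):
        f = centroid_features(self.spmap, DensityParams(feature_mode="ifs"))
        assert f.shape == (2, 3)

    def test_zero_scale_annihilates_spatial(self):
        f = centroid_features(
            self.spmap, DensityParams(feature_mode="ifs+spatial", spatial_scale=0.0)
        )
        assert f.shape == (2, 5)
        assert np.all(f[:, 3:] == 0.0)

    def test_centered_superpixel_maps_to_half(self):
        labels = np.zeros((20, 20), dtype=int)
        spmap = make_spmap(labels, np.full((20, 20), 0.5))
        f = centroid_features(spmap, DensityParams(feature_mode="ifs+spatial", spatial_scale=1.0))
        assert f[0, 3:] == pytest.approx([9.5 / 20, 9.5 / 20])


class TestDBSCAN:
    def test_identical_points_single_cluster(self):
        f = np.zeros((5, 3))
        out = dbscan_superpixels(f, DensityParams(delta=0.1, min_neighbors=5))
        assert out.n_clusters == 1
        assert np.all(out.role == CORE)
        assert np.all(out.cluster_id == 0)

    def test_isolated_point_is_noise(self):
        out = dbscan_superpixels(np.zeros((1, 3)), DensityParams(delta=0.1, min_neighbors=2))
        assert out.n_clusters == 0
        assert out.role[0] == NOISE and out.cluster_id[0] == -1

    def test_two_groups_on_a_line(self):
        f = np.array([[0.0], [0.1], [0.2], [5.0], [5.1]])
        out = dbscan_superpixels(f, DensityParams(delta=0.15, min_neighbors=2))
        assert out.n_clusters == 2
        assert np.array_equal(out.cluster_id, [0, 0, 0, 1, 1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 40))
        f = r.uniform(0, 1, size=(n, int(r.integers(1, 5))))
        delta = float(r.uniform(0.05, 0.4))
        minn = int(r.integers(2, 6))
        got = dbscan_superpixels(f, DensityParams(delta=delta, min_neighbors=minn))
        ref_partition, ref_core, ref_noise = brute_dbscan(f, delta, minn)
        got_partition = frozenset(
            frozenset(np.flatnonzero((got.cluster_id == c) & (got.role == CORE)).tolist())
            for c in range(got.n_clusters)
        ) - {frozenset()}
        assert got_partition == ref_partition
        assert np.array_equal(got.role == CORE, ref_core)
        assert set(np.flatnonzero(got.role == NOISE).tolist()) == ref_noise

    def test_border_points_adopt_core_neighbor_cluster(self):
        f = np.array([[0.0], [0.1], [0.2], [0.35]])
        out = dbscan_superpixels(f, DensityParams(delta=0.15, min_neighbors=3))
        assert np.array_equal(out.role, [BORDER, CORE, CORE, BORDER])
        assert np.array_equal(out.cluster_id, [0, 0, 0, 0])

    def test_order_invariance_of_core_structure(self, rng):
        f = rng.uniform(0, 1, size=(30, 3))
        params = DensityParams(delta=0.25, min_neighbors=3)
        a = dbscan_superpixels(f, params)
        perm = rng.permutation(30)
        b = dbscan_superpixels(f[perm], params)
        assert np.array_equal(a.role[perm] == CORE, b.role == CORE)
        assert np.array_equal(a.role[perm] == NOISE, b.role == NOISE)
        # core partition identical up to relabeling
        for c in range(a.n_clusters):
            members = np.flatnonzero((a.cluster_id == c) & (a.role == CORE))
            bids = {b.cluster_id[np.flatnonzero(perm == m)[0]] for m in members}
            assert len(bids) == 1

    def test_sklearn_cross_check(self, rng):
        from sklearn.cluster import DBSCAN

        f = rng.uniform(0, 1, size=(60, 4))
        params = DensityParams(delta=0.3, min_neighbors=4)
        got = dbscan_superpixels(f, params)
        sk = DBSCAN(eps=params.delta, min_samples=params.min_neighbors).fit(f)
        sk_core = np.zeros(60, dtype=bool)
        sk_core[sk.core_sample_indices_] = True
        assert np.array_equal(got.role == CORE, sk_core)
        assert np.array_equal(got.cluster_id == -1, sk.labels_ == -1)
        # core points in the same sklearn cluster share ours, and vice versa
        for c in set(sk.labels_[sk_core]):
            ours = got.cluster_id[sk_core & (sk.labels_ == c)]
            assert np.unique(ours).size == 1


class TestMassMask:
    def _two_region_map(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:15, 5:15] = 1  # dark square "mass"
        img = np.where(labels == 1, 50.0, 170.0)
        mu = np.where(labels == 1, 0.1, 0.9)
        return make_spmap(labels, mu), img

    def test_darkest_cluster_wins(self):
        spmap, img = self._two_region_map()
        out = dbscan_superpixels(
            centroid_features(spmap, DensityParams(feature_mode="ifs")),
            DensityParams(delta=0.05, min_neighbors=1),
        )
        mask = extract_mass_mask(spmap, out, img)
        assert np.array_equal(mask, spmap.labels == 1)

    def test_single_cluster_taken_whole(self):
        spmap, img = self._two_region_map()
        out = dbscan_superpixels(
            centroid_features(spmap, DensityParams(feature_mode="ifs")),
            DensityParams(delta=3.0, min_neighbors=1),
        )
        assert out.n_clusters == 1
        mask = extract_mass_mask(spmap, out, img)
        assert mask.all()

    def test_largest_component_survives(self):
        labels = np.zeros((30, 30), dtype=int)
        labels[8:22, 8:22] = 1  # main dark blob
        labels[1:3, 1:25] = 2  # thin dark rim artifact, smaller area
        img = np.where(labels > 0, 50.0, 170.0)
        mu = np.where(labels > 0, 0.1, 0.9)
        spmap = make_spmap(labels, mu)
        out = dbscan_superpixels(
            centroid_features(spmap, DensityParams(feature_mode="ifs")),
            DensityParams(delta=0.05, min_neighbors=1),
        )
        mask = extract_mass_mask(spmap, out, img)
        assert np.array_equal(mask, labels == 1)

    def test_all_noise_gives_empty_mask(self):
        labels = np.arange(4).reshape(2, 2)
        spmap = make_spmap(labels, np.array([[0.1, 0.4], [0.7, 0.9]]))
        out = dbscan_superpixels(
            centroid_features(spmap, DensityParams(feature_mode="ifs")),
            DensityParams(delta=0.01, min_neighbors=2),
        )
        assert out.n_clusters == 0
        mask = extract_mass_mask(spmap, out, np.zeros((2, 2)) + np.arange(2))
        assert not mask.any()
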