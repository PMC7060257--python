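import numpy as np
import pytest

from svdmap import (
    build_model_map,
    cluster_spectra,
    decompose,
    embed_points,
    kmeans_cluster,
    lorentzian,
    minor_component_mask,
    remove_outliers,
)
from svdmap.vspace_clustering import OutlierCapError, PointSet

from conftest import small_spec


def cosine(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def make_pointset(X, excluded=None):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    return PointSet(coordinates=X, spatial_coords=coords, excluded=excluded)


class TestEmbed:
    def test_one_dimensional_embedding_equals_v1(self, distinct_small_svd):
        pts = embed_points(distinct_small_svd, 1)
        np.testing.assert_array_equal(pts.coordinates[:, 0], distinct_small_svd.amplitudes[0])

    def test_columns_are_orthonormal(self, distinct_small_svd):
        pts = embed_points(distinct_small_svd, 2)
        np.testing.assert_allclose(pts.coordinates.T @ pts.coordinates, np.eye(2), atol=1e-10)

    def test_distinct_model_forms_three_separated_groups(self, distinct_small, distinct_small_svd):
        # background / circle-1 / circle-2 are far apart in V1-V2 space:
        # the smallest distance between group centers exceeds five times the
        # largest within-group spread
        spec = small_spec("distinct")
        pts = embed_points(distinct_small_svd, 2)
        r = np.hypot(distinct_small.coords[:, 0], distinct_small.coords[:, 1])
        g1 = np.abs(r - spec.circle1_radius) <= spec.radial_halfwidth_rect
        g2 = np.abs(r - spec.circle2_radius) <= spec.radial_halfwidth_rect
        groups = [pts.coordinates[g1], pts.coordinates[g2], pts.coordinates[~(g1 | g2)]]
        centers = [g.mean(axis=0) for g in groups]
        spreads = [np.linalg.norm(g - c, axis=1).max() for g, c in zip(groups, centers)]
        dists = [
            np.linalg.norm(centers[i] - centers[j])
            for i in range(3) for j in range(i + 1, 3)
        ]
        assert min(dists) > 5 * max(spreads)

    def test_n_e_bounds(self, distinct_small_svd):
        with pytest.raises(ValueError):
            embed_points(distinct_small_svd, 0)


class TestOutliers:
    def test_clean_model_keeps_every_point(self, distinct_small_svd):
        pts = remove_outliers(embed_points(distinct_small_svd, 2), c=10.0)
        assert pts.excluded.sum() == 0

    def test_single_spike_spectrum_is_flagged(self, rng):
        # a noise-dominated map with one wildly intense spectrum: only the
        # spiked point lands out of range in V-space
        from svdmap import HyperMap, SpectralAxis

        axis = SpectralAxis(np.linspace(1000.0, 1100.0, 64))
        xs = np.arange(20, dtype=float)
        X, Y = np.meshgrid(xs, xs)
        spectra = 1.0 + 0.1 * rng.normal(size=(400, 64))
        idx = 137
        spectra[idx] *= 1000.0
        hmap = HyperMap(axis=axis, coords=np.column_stack([X.ravel(), Y.ravel()]),
                        spectra=spectra)
        pts = remove_outliers(embed_points(decompose(hmap), 2), c=10.0)
        assert pts.excluded.sum() == 1
        assert pts.excluded[idx]

    def test_mass_spikes_trip_the_safety_cap(self, rng):
        X = rng.normal(size=(100, 2))
        X[:20] *= 500.0  # 20% wild points
        with pytest.raises(OutlierCapError):
            remove_outliers(make_pointset(X), c=10.0)

    def test_zero_mad_coordinate_cannot_flag(self, rng):
        X = np.column_stack([np.zeros(50), rng.normal(size=50)])
        pts = remove_outliers(make_pointset(X), c=10.0)
        assert pts.excluded.sum() == 0  # constant coordinate is skipped


class TestKMeans:
    def test_k1_center_is_mean_and_inertia_total_scatter(self, rng):
        X = rng.normal(size=(40, 3))
        res = kmeans_cluster(make_pointset(X), k=1, seed=0)
        np.testing.assert_allclose(res.centers[0], X.mean(axis=0), atol=1e-12)
        assert res.inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())
        assert set(res.labels) == {1}

    def test_distinct_model_clusters_exactly(self, distinct_small, distinct_small_svd):
        spec = small_spec("distinct")
        res = kmeans_cluster(embed_points(distinct_small_svd, 2), k=3, seed=12)
        r = np.hypot(distinct_small.coords[:, 0], distinct_small.coords[:, 1])
        g1 = np.abs(r - spec.circle1_radius) <= spec.radial_halfwidth_rect
        g2 = np.abs(r - spec.circle2_radius) <= spec.radial_halfwidth_rect
        bg = ~(g1 | g2)
        # zero mislabeled points: every true group maps onto exactly one label
        for mask in (g1, g2, bg):
            assert len(set(res.labels[mask])) == 1
        # canonical numbering: background is the biggest cluster
        assert set(res.labels[bg]) == {1}

    def test_duplicated_points_get_identical_labels(self, rng):
        X = rng.normal(size=(30, 2)) + np.repeat([[0, 0], [8, 8], [-8, 8]], 10, axis=0)
        doubled = np.vstack([X, X])
        res = kmeans_cluster(make_pointset(doubled), k=3, seed=5)
        np.testing.assert_array_equal(res.labels[:30], res.labels[30:])

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 2))
        a = kmeans_cluster(make_pointset(X), k=4, seed=9)
        b = kmeans_cluster(make_pointset(X), k=4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_labels_invariant_under_point_permutation(self, rng):
        X = rng.normal(size=(60, 2)) + np.repeat([[0, 0], [10, 0], [0, 10]], 20, axis=0)
        perm = rng.permutation(60)
        a = kmeans_cluster(make_pointset(X), k=3, seed=2)
        b = kmeans_cluster(make_pointset(X[perm]), k=3, seed=2)
        np.testing.assert_array_equal(a.labels[perm], b.labels)

    def test_excluded_points_keep_label_zero(self, rng):
        X = rng.normal(size=(20, 2))
        excluded = np.zeros(20, dtype=bool)
        excluded[[3, 7]] = True
        res = kmeans_cluster(make_pointset(X, excluded), k=2, seed=1)
        assert np.all(res.labels[[3, 7]] == 0)
        assert np.all(res.labels[~excluded] >= 1)

    def test_k_bounds(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            kmeans_cluster(make_pointset(X), k=6, seed=0)
        with pytest.raises(ValueError):
            kmeans_cluster(make_pointset(X), k=0, seed=0)


class TestClusterSpectra:
    def test_k1_spectrum_is_map_average(self, distinct_small, distinct_small_svd):
        res = kmeans_cluster(embed_points(distinct_small_svd, 1), k=1, seed=0)
        spectra = cluster_spectra(distinct_small, res)
        np.testing.assert_allclose(spectra[0], distinct_small.spectra.mean(axis=0), atol=1e-12)

    def test_distinct_minor_peak_is_one_percent_of_major(self, distinct_small, distinct_small_svd):
        res = kmeans_cluster(embed_points(distinct_small_svd, 2), k=3, seed=12)
        spectra = cluster_spectra(distinct_small, res)
        peaks = np.sort(spectra.max(axis=1))
        assert peaks[0] == pytest.approx(0.0, abs=1e-12)  # flat background
        assert 100.0 * peaks[1] / peaks[2] == pytest.approx(1.0, abs=0.1)

    def test_spectra_are_convex_combinations_of_members(self, distinct_small, distinct_small_svd):
        res = kmeans_cluster(embed_points(distinct_small_svd, 2), k=3, seed=12)
        spectra = cluster_spectra(distinct_small, res)
        for c in range(1, 4):
            member = distinct_small.spectra[res.members(c)]
            assert np.all(spectra[c - 1] >= member.min(axis=0) - 1e-12)
            assert np.all(spectra[c - 1] <= member.max(axis=0) + 1e-12)

    def test_distinct_clusters_recover_pure_components(self, distinct_small, distinct_small_svd):
        spec = small_spec("distinct")
        res = kmeans_cluster(embed_points(distinct_small_svd, 2), k=3, seed=12)
        spectra = cluster_spectra(distinct_small, res)
        pure1 = lorentzian(spec.axis, spec.peak1)
        pure2 = lorentzian(spec.axis, spec.peak2)
        sims1 = [cosine(s, pure1) for s in spectra]
        sims2 = [cosine(s, pure2) for s in spectra]
        assert max(sims1) > 0.999
        assert max(sims2) > 0.999

    @pytest.mark.parametrize("kind", ["overlapping", "on_top"])
    def test_mixed_models_never_yield_a_pure_minor_spectrum(self, kind):
        # the central negative claim: with spatial overlap every cluster
        # spectrum is a mixture, never the pure minor component
        spec = small_spec(kind)
        hmap = build_model_map(spec)
        svd = decompose(hmap)
        res = kmeans_cluster(embed_points(svd, 2), k=3, seed=12)
        spectra = cluster_spectra(hmap, res)
        pure2 = lorentzian(spec.axis, spec.peak2)
        assert all(cosine(s, pure2) < 0.999 for s in spectra)

    def test_reconstructed_mode_equals_original_at_true_rank(
        self, distinct_small, distinct_small_svd
    ):
        res = kmeans_cluster(embed_points(distinct_small_svd, 2), k=3, seed=12)
        orig = cluster_spectra(distinct_small, res, mode="original").copy()
        recon = cluster_spectra(
            distinct_small, res, mode="reconstructed", svd=distinct_small_svd, n_e=2
        )
        # the noiseless map is exactly rank 2, so filtering changes nothing
        np.testing.assert_allclose(recon, orig, atol=1e-10)

    def test_empty_cluster_warns_and_zeroes(self, distinct_small, distinct_small_svd, rng):
        res = kmeans_cluster(embed_points(distinct_small_svd, 2), k=3, seed=12)
        res.labels[res.labels == 3] = 2  # fabricate an empty cluster
        with pytest.warns(UserWarning, match="empty"):
            spectra = cluster_spectra(distinct_small, res)
        assert np.all(spectra[2] == 0)
        assert res.empty_clusters == (3,)
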