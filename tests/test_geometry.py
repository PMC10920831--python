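"""Population geometry: PCA embedding, silhouette, conservation distances."""

import numpy as np
import pytest
from scipy import stats

from feedscope import (
    GeneratorConfig,
    TraceMatrix,
    center_distance,
    chance_silhouette,
    concatenate_coregistered,
    conservation_test,
    cross_assay_distances,
    embed_pca,
    generate_assay_pair,
    mahalanobis_cross_assay,
    rasterize,
    silhouette,
)
from feedscope.datatypes import ClusterEmbedding, CoRegistrationMap

import oracles


def labeled_blobs(rng, centers, n_per=20, sd=0.3):
    coords, labels = [], []
    for lab, c in centers.items():
        coords.append(rng.normal(0, sd, size=(n_per, len(c))) + np.asarray(c))
        labels += [lab] * n_per
    return ClusterEmbedding(coords=np.vstack(coords), labels=np.array(labels))


def session_embedding(session):
    labels = rasterize(session.epochs, session.traces.time)
    return embed_pca(session.traces, labels)


class TestEmbedPCA:
    def test_three_dim_data_recovered(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=(3, 500))
        mix = rng.normal(size=(10, 3))
        tr = TraceMatrix([f"c{i}" for i in range(10)], 7.5, mix @ latent)
        labels = np.array(
            ["approach", "eat", "rear"] * 166 + ["approach", "eat"]
        )
        emb = embed_pca(tr, labels, zscore=False)
        assert emb.coords.shape == (500, 3)
        # noiseless 3-D data: the top 3 PCs capture everything
        assert emb.explained_variance[:3].sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_cells_same_subspace(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 300))
        labels = np.array(["approach", "eat", "rear"] * 100)
        ids = [f"c{i}" for i in range(5)]
        emb1 = embed_pca(TraceMatrix(ids, 7.5, values), labels, zscore=False)
        dup = np.vstack([values, values])
        emb2 = embed_pca(
            TraceMatrix(ids + [f"d{i}" for i in range(5)], 7.5, dup),
            labels,
            zscore=False,
        )
        # duplication scales the space by sqrt(2) but preserves geometry
        ratio = np.linalg.norm(emb2.coords) / np.linalg.norm(emb1.coords)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=1e-6)
        corr = np.corrcoef(emb1.coords[:, 0], emb2.coords[:, 0])[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(8, 200))
        labels = np.array(["approach", "eat", "rear", "other"] * 50)
        emb = embed_pca(TraceMatrix([f"c{i}" for i in range(8)], 7.5, values),
                        labels, zscore=False)
        X = values.T - values.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
        order = np.argsort(evals)[::-1][:3]
        scores = X @ evecs[:, order]
        keep = np.isin(labels, ("approach", "eat", "rear"))
        for k in range(3):
            r = np.corrcoef(emb.coords[:, k], scores[keep][:, k])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_cells_rejected(self):
        tr = TraceMatrix(["a", "b"], 7.5, np.random.default_rng(0).normal(size=(2, 50)))
        labels = np.array(["approach", "eat", "rear", "other"] * 12 + ["eat", "eat"])
        with pytest.raises(ValueError, match="components"):
            embed_pca(tr, labels, n_components=3)


class TestConcatenate:
    def test_identity_map_duplicates_columns(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(4, 100))
        ids = [f"c{i}" for i in range(4)]
        tr = TraceMatrix(ids, 7.5, values)
        joint, tags = concatenate_coregistered(
            tr, tr, CoRegistrationMap([(i, i) for i in ids])
        )
        np.testing.assert_array_equal(joint.values, np.hstack([values, values]))
        assert list(tags) == ["A"] * 100 + ["B"] * 100

    def test_empty_map_rejected(self):
        tr = TraceMatrix(["a"], 7.5, np.zeros((1, 10)))
        with pytest.raises(ValueError, match="empty"):
            concatenate_coregistered(tr, tr, CoRegistrationMap([]))

    def test_permuted_map_row_lookup(self):
        rng = np.random.default_rng(4)
        va = rng.normal(size=(6, 40))
        vb = rng.normal(size=(6, 50))
        ids = [f"c{i}" for i in range(6)]
        perm = rng.permutation(6)
        coreg = CoRegistrationMap([(ids[i], ids[perm[i]]) for i in range(6)])
        joint, _ = concatenate_coregistered(
            TraceMatrix(ids, 7.5, va), TraceMatrix(ids, 7.5, vb), coreg
        )
        for row, (a, b) in enumerate(coreg.pairs):
            np.testing.assert_array_equal(joint.values[row, :40], va[ids.index(a)])
            np.testing.assert_array_equal(joint.values[row, 40:], vb[ids.index(b)])

    def test_missing_id_named(self):
        tr = TraceMatrix(["a"], 7.5, np.zeros((1, 10)))
        with pytest.raises(KeyError, match="zzz"):
            concatenate_coregistered(tr, tr, CoRegistrationMap([("a", "zzz")]))


class TestSilhouette:
    def test_far_separated_clusters_near_one(self):
        rng = np.random.default_rng(5)
        emb = labeled_blobs(rng, {"eat": (0, 0), "approach": (100, 0)}, sd=0.1)
        assert silhouette(emb) > 0.99

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(300, 3))
        labels = rng.choice(["eat", "approach", "rear"], size=300)
        assert abs(silhouette(ClusterEmbedding(coords=coords, labels=labels))) < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        coords = rng.normal(size=(n, int(rng.integers(1, 4))))
        labels = rng.choice(["a", "b", "c"][: rng.integers(2, 4)], size=n)
        if len(set(labels)) < 2:
            labels[0] = "a" if labels[1] != "a" else "b"
        got = silhouette(ClusterEmbedding(coords=coords, labels=labels))
        want = oracles.silhouette_brute(coords, labels)
        assert got == pytest.approx(want, abs=1e-12)

    def test_agrees_with_sklearn_on_regular_instances(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(55)
        for _ in range(10):
            coords = rng.normal(size=(40, 3))
            labels = np.array(["a", "b", "c", "d"] * 10)
            got = silhouette(ClusterEmbedding(coords=coords, labels=labels))
            assert got == pytest.approx(
                silhouette_score(coords, labels), abs=1e-10
            )

    def test_singleton_cluster_scores_zero_with_warning(self):
        coords = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0]])
        labels = np.array(["a", "a", "b"])
        from feedscope import silhouette_samples

        with pytest.warns(UserWarning, match="size 1"):
            s = silhouette_samples(ClusterEmbedding(coords=coords, labels=labels))
        assert s[2] == 0.0


class TestChanceSilhouette:
    def test_separated_clusters_above_null(self):
        rng = np.random.default_rng(7)
        emb = labeled_blobs(rng, {"eat": (0, 0), "approach": (50, 0)}, sd=0.2)
        res = chance_silhouette(emb, n_shuffles=100, seed=0)
        assert res["percentile"] == 100.0
        assert res["observed"] > res["null"].max()

    def test_fixed_seed_identical_null(self):
        rng = np.random.default_rng(8)
        emb = labeled_blobs(rng, {"eat": (0, 0), "approach": (1, 0)})
        r1 = chance_silhouette(emb, n_shuffles=50, seed=3)
        r2 = chance_silhouette(emb, n_shuffles=50, seed=3)
        np.testing.assert_array_equal(r1["null"], r2["null"])

    def test_percentile_calibrated_under_null(self):
        """With already-random labels the observed percentile is uniform."""
        rng = np.random.default_rng(9)
        pcts = []
        for _ in range(200):
            coords = rng.normal(size=(40, 2))
            labels = np.array(["a"] * 20 + ["b"] * 20)
            rng.shuffle(labels)
            res = chance_silhouette(
                ClusterEmbedding(coords=coords, labels=labels),
                n_shuffles=50,
                seed=int(rng.integers(2**31)),
            )
            pcts.append((res["percentile"] + rng.uniform(0, 2)) / 102.0)
        assert stats.kstest(pcts, "uniform").pvalue > 0.01


class TestMahalanobis:
    def test_reference_mean_distance_zero(self):
        rng = np.random.default_rng(10)
        ref = rng.normal(size=(50, 3))
        d = mahalanobis_cross_assay(ref, ref.mean(axis=0))
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_equals_euclidean(self):
        rng = np.random.default_rng(11)
        # enormous sample so the sample covariance ~ identity
        ref = rng.normal(size=(200_000, 2))
        q = np.array([[3.0, 4.0]])
        d = mahalanobis_cross_assay(ref, q)
        euclid = np.linalg.norm(q - ref.mean(axis=0))
        assert d[0] == pytest.approx(euclid, rel=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_solve_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(40, 5))
        query = rng.normal(size=(15, 5))
        got = mahalanobis_cross_assay(ref, query)
        want = oracles.mahalanobis_solve(ref, query)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(12)
        ref = rng.normal(size=(60, 4))
        query = rng.normal(size=(10, 4))
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4)
        d1 = mahalanobis_cross_assay(ref, query)
        d2 = mahalanobis_cross_assay(ref @ A.T + b, query @ A.T + b)
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_insufficient_reference_rejected(self):
        with pytest.raises(ValueError, match="more samples"):
            mahalanobis_cross_assay(np.zeros((3, 5)), np.zeros((1, 5)))


class TestCenterDistance:
    def test_identical_points_zero(self):
        assert np.all(center_distance(np.ones((5, 3))) == 0.0)

    def test_two_points_unit(self):
        d = center_distance(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        np.testing.assert_allclose(d, [1.0, 1.0])

    def test_matches_norm_oracle(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(30, 4))
        want = [np.linalg.norm(p - pts.mean(axis=0)) for p in pts]
        np.testing.assert_allclose(center_distance(pts), want, atol=1e-12)


class TestConservation:
    def test_identical_samples_p_near_one(self):
        x = np.arange(20.0)
        res = conservation_test(x, x.copy())
        assert res.p_value > 0.9

    def test_fully_separated_p_tiny(self):
        res = conservation_test(np.arange(100.0), np.arange(100.0) + 1000.0)
        assert res.p_value < 1e-6
        assert res.direction == "eat more conserved"

    def test_statistic_matches_rank_enumeration(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            res = conservation_test(x, y)
            # z from ranksums relates monotonically to the exact U statistic
            u, p_exact = oracles.rank_sum_exact(x, y)
            p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue
            assert p_exact == pytest.approx(p_scipy, abs=1e-12)
            assert np.sign(res.statistic) == np.sign(u - 6 * 7 / 2.0) or u == 6 * 7 / 2.0

    def test_shared_eat_ensemble_recovered(self):
        """Assay pairs with a shared eating ensemble and independent approach
        ensembles: eating clusters sit closer across assays."""
        cfg = GeneratorConfig(n_cells=30, duration=600.0)
        wins = 0
        for seed in range(10):
            a, b, m = generate_assay_pair(cfg, overlap={"eat"}, seed=seed)
            joint, tags = concatenate_coregistered(a.traces, b.traces, m)
            lab = np.concatenate(
                [rasterize(a.epochs, a.traces.time), rasterize(b.epochs, b.traces.time)]
            )
            X = joint.values.T
            d_eat = cross_assay_distances(X, tags, lab, "eat")
            d_app = cross_assay_distances(X, tags, lab, "approach")
            res = conservation_test(d_eat, d_app)
            wins += res.direction == "eat more conserved" and res.p_value < 0.05
        assert wins >= 9
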