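import numpy as np
import pandas as pd
import pytest

from leida.phase_dfc import canonicalize_sign
from leida.states import (PooledEigenvectors, StateMeanDfc, StateModel,
                          cluster_states, dunn_score, pool_eigenvectors,
                          reconstruct_static_fc, sc_similarity, select_k,
                          state_mean_dfc)
from leida.synthetic import planted_sign_patterns


def sample_rows(patterns, counts, noise_deg, seed):
    """Pooled rows drawn around unit patterns with angular (tangent) noise."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    sigma = np.deg2rad(noise_deg)
    for c, (p, n) in enumerate(zip(patterns, counts), start=1):
        p = p / np.linalg.norm(p)
        for _ in range(n):
            v = p + sigma * rng.normal(size=p.size)
            rows.append(canonicalize_sign(v / np.linalg.norm(v)))
            labels.append(c)
    rows = np.asarray(rows)
    order = rng.permutation(len(rows))
    pooled = PooledEigenvectors(rows[order],
                                np.array([f"s{i % 3}" for i in range(len(rows))]),
                                np.arange(len(rows)))
    return pooled, np.asarray(labels)[order]


def agreement(labels_a, labels_b):
    """Best-permutation label agreement."""
    from itertools import permutations
    ka = labels_a.max()
    best = 0.0
    for perm in permutations(range(1, ka + 1)):
        mapped = np.array([perm[l - 1] for l in labels_a])
        best = max(best, np.mean(mapped == labels_b))
    return best


class TestClusterStates:
    def test_recovers_planted_patterns_exactly_without_noise(self):
        pats = np.eye(6)[:3]  # mutually orthogonal unit patterns
        pooled, truth = sample_rows(pats, [20, 30, 25], 0.0, seed=1)
        model = cluster_states(pooled, 3, replicates=5, seed=2)
        cos = np.abs(model.centroids @ pats.T)
        assert (cos.max(axis=1) >= 1 - 1e-10).all()
        assert agreement(model.labels, truth) == 1.0

    @pytest.mark.parametrize("distance", ["cosine", "euclidean"])
    def test_recovers_noisy_patterns(self, distance):
        pats = planted_sign_patterns(16, 3, margin=6)
        pooled, _ = sample_rows(pats, [40, 40, 40], 5.0, seed=3)
        model = cluster_states(pooled, 3, replicates=10, distance=distance, seed=4)
        cos = np.abs(model.centroids @ (pats / np.linalg.norm(pats, axis=1, keepdims=True)).T)
        assert (cos.max(axis=1) >= 0.98).all()

    def test_fixed_seed_is_deterministic(self):
        pats = np.eye(5)[:2]
        pooled, _ = sample_rows(pats, [30, 30], 8.0, seed=5)
        a = cluster_states(pooled, 2, replicates=4, seed=11)
        b = cluster_states(pooled, 2, replicates=4, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.dunn == b.dunn

    def test_occupancy_is_exact_count_ratio_and_sorted(self):
        pats = np.eye(5)[:2]
        pooled, _ = sample_rows(pats, [50, 20], 3.0, seed=6)
        model = cluster_states(pooled, 2, replicates=4, seed=7)
        counts = np.bincount(model.labels, minlength=3)[1:]
        np.testing.assert_allclose(model.occupancy, counts / counts.sum(), atol=0)
        assert model.occupancy[0] >= model.occupancy[1]

    def test_cosine_agrees_with_sklearn_on_unit_norm_data(self):
        """On unit vectors cosine and euclidean k-means share the optimum."""
        from sklearn.cluster import KMeans
        pats = planted_sign_patterns(16, 3, margin=6)
        pooled, _ = sample_rows(pats, [30, 30, 30], 3.0, seed=8)
        ours = cluster_states(pooled, 3, replicates=10, distance="cosine", seed=9)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(pooled.matrix)
        assert agreement(ours.labels, sk + 1) == 1.0


class TestDunn:
    def test_two_tight_1d_clusters(self):
        x = np.array([[0.0], [0.1], [1.0], [1.1]])
        labels = np.array([1, 1, 2, 2])
        assert dunn_score(x, labels, "euclidean") == pytest.approx(9.0)

    def test_singleton_clusters_give_infinity(self):
        x = np.array([[0.0], [1.0]])
        assert dunn_score(x, np.array([1, 2]), "euclidean") == np.inf

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            dunn_score(np.zeros((3, 2)), np.array([1, 1, 1]), "euclidean")

    @pytest.mark.parametrize("distance", ["cosine", "euclidean"])
    def test_matches_brute_force_oracle(self, distance, rng):
        x = rng.normal(size=(40, 4))
        labels = rng.integers(1, 4, size=40)

        def d(a, b):
            if distance == "euclidean":
                return np.linalg.norm(a - b)
            return 1 - a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        inter, diam = np.inf, 0.0
        for i in range(40):
            for j in range(40):
                if i == j:
                    continue
                dij = d(x[i], x[j])
                if labels[i] == labels[j]:
                    diam = max(diam, dij)
                else:
                    inter = min(inter, dij)
        assert dunn_score(x, labels, distance) == pytest.approx(inter / diam, abs=1e-12)


class TestSelectK:
    @pytest.mark.parametrize("k_true", [2, 5])
    def test_planted_k_is_dunn_argmax(self, k_true):
        pats = planted_sign_patterns(32, k_true)
        pooled, _ = sample_rows(pats, [60] * k_true, 4.0, seed=20 + k_true)
        best, table = select_k(pooled, range(2, 9), replicates=5, seed=21)
        assert best.k == k_true
        assert set(table.columns) >= {"k", "dunn", "occupancy_entropy"}

    def test_ties_break_toward_smaller_k(self, monkeypatch):
        import leida.states as states_mod

        def fake_cluster(pooled, k, replicates=1, distance="cosine", seed=0):
            return StateModel(k=k, centroids=np.eye(max(k, 2))[:k],
                              labels=np.tile(np.arange(1, k + 1), 4),
                              dunn=1.0, occupancy=np.full(k, 1.0 / k))

        monkeypatch.setattr(states_mod, "cluster_states", fake_cluster)
        pooled = PooledEigenvectors(np.eye(8), np.repeat("s", 8), np.arange(8))
        best, _ = states_mod.select_k(pooled, [4, 2, 3], replicates=1, seed=0)
        assert best.k == 2

    def test_noise_degrades_recovery_monotonically(self):
        pats = planted_sign_patterns(16, 3, margin=6)
        unit = pats / np.linalg.norm(pats, axis=1, keepdims=True)
        scores = []
        for noise in (2.0, 10.0, 30.0):
            pooled, _ = sample_rows(pats, [40] * 3, noise, seed=31)
            model = cluster_states(pooled, 3, replicates=8, seed=32)
            scores.append(np.abs(model.centroids @ unit.T).max(axis=1).mean())
        assert scores[0] > scores[1] > scores[2]


class TestStateMeanDfc:
    def test_identical_frames_average_to_themselves(self):
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = state_mean_dfc([m, m, m], [1, 1, 1], k=1)
        np.testing.assert_array_equal(out.per_state[0], m)

    def test_two_frames_give_midpoint(self):
        a = np.eye(2)
        b = np.ones((2, 2))
        out = state_mean_dfc([a, b], [1, 1], k=1)
        np.testing.assert_allclose(out.per_state[0], (a + b) / 2)

    def test_matches_accumulation_oracle(self, rng):
        frames = rng.uniform(-1, 1, size=(20, 4, 4))
        labels = rng.integers(1, 4, size=20)
        out = state_mean_dfc(frames, labels, k=3)
        for c in range(1, 4):
            np.testing.assert_allclose(out.per_state[c - 1],
                                       frames[labels == c].mean(axis=0), atol=1e-13)

    def test_state_without_frames_rejected(self):
        with pytest.raises(ValueError, match="zero frames"):
            state_mean_dfc([np.eye(2)], [1], k=2)


def make_model(centroids, occupancy, labels=None):
    centroids = np.asarray(centroids, dtype=float)
    k = centroids.shape[0]
    occupancy = np.asarray(occupancy, dtype=float)
    if labels is None:
        labels = np.tile(np.arange(1, k + 1), 4)
    return StateModel(k=k, centroids=centroids, labels=labels, dunn=1.0,
                      occupancy=occupancy)


class TestReconstruction:
    def test_single_state_is_weighted_outer_product(self):
        v = np.full(4, 0.5)
        rec = reconstruct_static_fc(make_model(v[None, :], [1.0]))
        np.testing.assert_allclose(rec.outer_product, np.outer(v, v), atol=1e-14)

    def test_equal_weights_average_two_outer_products(self):
        a = np.array([1.0, 0, 0, 0])
        b = np.array([0, 1.0, 0, 0])
        model = make_model(np.vstack([a, b]), [0.5, 0.5],
                           labels=np.array([1, 2, 1, 2]))
        rec = reconstruct_static_fc(model)
        np.testing.assert_allclose(rec.outer_product,
                                   (np.outer(a, a) + np.outer(b, b)) / 2)

    def test_outer_product_reconstruction_is_symmetric_psd(self, rng):
        c = rng.normal(size=(3, 6))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        occ = np.sort(rng.dirichlet(np.ones(3)))[::-1]
        rec = reconstruct_static_fc(make_model(c, occ, labels=np.array([1, 2, 3, 1])))
        np.testing.assert_array_equal(rec.outer_product, rec.outer_product.T)
        assert np.linalg.eigvalsh(rec.outer_product).min() >= -1e-12

    def test_sign_flips_and_relabeling_leave_reconstruction_unchanged(self, rng):
        c = rng.normal(size=(3, 5))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        occ = np.array([0.5, 0.3, 0.2])
        base = reconstruct_static_fc(make_model(c, occ, np.array([1, 2, 3, 1])))
        flipped = reconstruct_static_fc(make_model(-c, occ, np.array([1, 2, 3, 1])))
        np.testing.assert_allclose(base.outer_product, flipped.outer_product,
                                   atol=1e-13)


class TestScSimilarity:
    def test_identity_orthogonal_and_formula(self, rng):
        fc = rng.uniform(-1, 1, size=(4, 4))
        fc = (fc + fc.T) / 2
        np.fill_diagonal(fc, 1.0)
        mean = StateMeanDfc(fc[None], np.array([3]))
        sc = np.abs(fc)
        np.fill_diagonal(sc, 0.0)
        iu = np.triu_indices(4, 1)
        expected = (sc[iu] @ fc[iu]) / (np.linalg.norm(sc[iu]) * np.linalg.norm(fc[iu]))
        assert sc_similarity(sc, mean)[0] == pytest.approx(expected, abs=1e-12)
        # SC proportional to |FC| upper triangle -> similarity with |FC| states is 1
        mean_abs = StateMeanDfc(np.abs(fc)[None], np.array([3]))
        assert sc_similarity(sc, mean_abs)[0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_upper_triangles(self):
        fc = np.eye(3)
        fc[0, 1] = fc[1, 0] = 0.8
        sc = np.zeros((3, 3))
        sc[0, 2] = sc[2, 0] = 1.0
        mean = StateMeanDfc(fc[None], np.array([1]))
        assert sc_similarity(sc, mean)[0] == pytest.approx(0.0, abs=1e-15)


class TestPooling:
    def test_pool_eigenvectors_stacks_with_provenance(self, tiny_cohort):
        from leida.phase_dfc import eigenvector_series
        _, subjects, _ = tiny_cohort
        series = [eigenvector_series(ts) for ts in subjects[:2]]
        pooled = pool_eigenvectors(series)
        assert pooled.n_rows == sum(s.n_frames for s in series)
        assert list(np.unique(pooled.subject_index)) == sorted(
            s.subject_id for s in series)
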