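"""Similarity graph, Laplacian spectrum, spectral seeding, Lloyd."""

from itertools import product

import numpy as np
import pytest

import graphmcdm as g
from graphmcdm.cluster import (
    SpectralEmbedding,
    _farthest_first,
    baseline_init,
    initial_centers,
    laplacian,
    lloyd,
    similarity_matrix,
    spectral_embedding,
)
from graphmcdm.errors import IdenticalAlternativesError, UnknownMethodError, \
    ValidationError


def two_blobs(rng=None, sep=10.0, noise=0.1, n_per=5):
    rng = rng or np.random.default_rng(0)
    a = rng.normal(0, noise, (n_per, 1))
    b = rng.normal(sep, noise, (n_per, 1))
    return np.vstack([a, b]), np.array([0] * n_per + [1] * n_per)


class TestSimilarity:
    def test_identical_points_have_unit_similarity(self):
        G = similarity_matrix(np.array([[1.0], [1.0], [3.0]]), sigma=2.0)
        assert G.S[0, 1] == pytest.approx(1.0)

    def test_characteristic_distance_gives_inverse_e(self):
        sigma = 1.7
        d = np.sqrt(2) * sigma  # ||x_i - x_j||^2 = 2 sigma^2
        G = similarity_matrix(np.array([[0.0], [d]]), sigma=sigma)
        assert G.S[0, 1] == pytest.approx(np.exp(-1))

    def test_auto_sigma_is_median_pairwise(self):
        # distances {3, 4, 1} -> median 3
        G = similarity_matrix(np.array([[0.0], [3.0], [4.0]]))
        assert G.sigma == pytest.approx(3.0)
        assert G.S[0, 1] == pytest.approx(np.exp(-9 / 18))

    def test_symmetry_and_range(self, rng):
        G = similarity_matrix(rng.normal(size=(8, 2)), sigma=1.0)
        assert np.allclose(G.S, G.S.T)
        assert np.all((G.S > 0) & (G.S <= 1))
        assert np.allclose(np.diag(G.S), 1.0)

    def test_all_identical_points_rejected_with_auto(self):
        with pytest.raises(IdenticalAlternativesError):
            similarity_matrix(np.zeros((4, 1)))


class TestLaplacian:
    def test_rows_sum_to_zero_and_psd(self, rng):
        G = similarity_matrix(rng.normal(size=(10, 2)), sigma=1.0)
        LP = laplacian(G)
        assert np.abs(LP.L.sum(axis=1)).max() <= 1e-10
        evals = np.linalg.eigvalsh(LP.L)
        assert evals.min() >= -1e-8

    def test_two_point_closed_form(self):
        s = 0.37
        S = np.array([[1.0, s], [s, 1.0]])
        LP = laplacian(S)
        assert LP.L == pytest.approx(np.array([[s, -s], [-s, s]]))
        assert np.linalg.eigvalsh(LP.L) == pytest.approx([0.0, 2 * s], abs=1e-12)

    def test_diagonal_convention_cancels(self, rng):
        G = similarity_matrix(rng.normal(size=(6, 1)), sigma=1.0)
        S0 = G.S.copy()
        S_nodiag = S0.copy()
        np.fill_diagonal(S_nodiag, 0.0)
        L_with = laplacian(S0).L
        L_without = laplacian(S_nodiag).L
        assert L_with == pytest.approx(L_without, abs=1e-12)


class TestSpectralEmbedding:
    def test_null_space_vector_for_connected_graph(self, rng):
        G = similarity_matrix(rng.normal(size=(7, 1)), sigma=5.0)
        E = spectral_embedding(laplacian(G), 1)
        assert E.eigenvalues[0] == pytest.approx(0.0, abs=1e-8)
        v = E.U[:, 0]
        assert np.all(v > 0) or np.all(v < 0)

    def test_component_count_equals_near_zero_eigenvalues(self):
        pts, _ = two_blobs(sep=100.0, noise=0.01)
        G = similarity_matrix(pts, sigma=0.5)
        E = spectral_embedding(laplacian(G), pts.shape[0])
        assert int((np.abs(E.eigenvalues) <= 1e-8).sum()) == 2

    def test_columns_orthonormal_ascending(self, rng):
        G = similarity_matrix(rng.normal(size=(9, 2)), sigma=1.0)
        E = spectral_embedding(laplacian(G), 4)
        assert E.U.T @ E.U == pytest.approx(np.eye(4), abs=1e-8)
        assert np.all(np.diff(E.eigenvalues) >= -1e-12)

    def test_matches_independent_eigensolver(self):
        S = np.array([[1.0, 0.8, 0.1], [0.8, 1.0, 0.3], [0.1, 0.3, 1.0]])
        LP = laplacian(S)
        E = spectral_embedding(LP, 3)
        evals, evecs = np.linalg.eig(LP.L)  # independent route: general solver
        order = np.argsort(evals.real)
        assert E.eigenvalues == pytest.approx(evals.real[order], abs=1e-10)
        for c in range(3):
            v = evecs.real[:, order[c]]
            got = E.U[:, c]
            assert min(np.abs(got - v).max(), np.abs(got + v).max()) <= 1e-8

    def test_sign_convention_deterministic(self, rng):
        G = similarity_matrix(rng.normal(size=(6, 1)), sigma=1.0)
        E = spectral_embedding(laplacian(G), 3)
        for c in range(3):
            i = np.argmax(np.abs(E.U[:, c]))
            assert E.U[i, c] > 0

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            spectral_embedding(np.zeros((3, 3)), 4)


class TestInitialCenters:
    def test_k_one_is_global_mean(self, rng):
        pts = rng.normal(size=(6, 2))
        G = similarity_matrix(pts, sigma=1.0)
        E = spectral_embedding(laplacian(G), 1)
        C = initial_centers(pts, E, 1)
        assert C[0] == pytest.approx(pts.mean(axis=0))

    def test_two_blob_exhaustive_oracle(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        G = similarity_matrix(pts, sigma=1.0)
        E = spectral_embedding(laplacian(G), 2)
        C = np.sort(initial_centers(pts, E, 2).ravel())
        # oracle: best 2-partition by within-cluster SSE, exhaustively
        best, best_sse = None, np.inf
        for assign in product([0, 1], repeat=4):
            assign = np.array(assign)
            if len(set(assign)) < 2:
                continue
            cent = [pts[assign == j].mean() for j in (0, 1)]
            sse = sum((pts[i, 0] - cent[assign[i]]) ** 2 for i in range(4))
            if sse < best_sse:
                best_sse, best = sse, [c for c in cent]
        assert C == pytest.approx(np.sort(best))
        assert C == pytest.approx([0.05, 10.05])

    def test_k_equals_m_every_point_is_a_center(self):
        pts = np.array([[0.0], [1.0], [5.0], [9.0]])
        G = similarity_matrix(pts, sigma=1.0)
        E = spectral_embedding(laplacian(G), 4)
        C = initial_centers(pts, E, 4)
        assert np.sort(C.ravel()) == pytest.approx(np.sort(pts.ravel()))


class TestLloyd:
    def test_k_one_converges_immediately_from_mean(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        res = lloyd(pts, pts.mean(axis=0, keepdims=True))
        assert res.iterations == 1 and res.converged
        assert res.centers[0, 0] == pytest.approx(2.0)
        assert res.inertia == pytest.approx(((pts - 2.0) ** 2).sum())

    def test_five_point_bruteforce_partition(self):
        pts = np.array([0.0, 0.1, 0.2, 10.0, 10.1])[:, None]
        res = lloyd(pts, np.array([[0.0], [9.0]]))
        assert list(res.labels) == [0, 0, 0, 1, 1]
        assert np.sort(res.centers.ravel()) == pytest.approx([0.1, 10.05])
        # oracle: exhaustive 2-partition SSE minimum
        best_sse = np.inf
        for assign in product([0, 1], repeat=5):
            assign = np.array(assign)
            if len(set(assign)) < 2:
                continue
            cent = [pts[assign == j].mean() for j in (0, 1)]
            sse = sum((pts[i, 0] - cent[assign[i]]) ** 2 for i in range(5))
            best_sse = min(best_sse, sse)
        assert res.inertia == pytest.approx(best_sse)

    def test_fixed_point_detected(self):
        pts = np.array([[0.0], [0.0], [4.0], [4.0]])
        res = lloyd(pts, np.array([[0.0], [4.0]]))
        assert res.converged and res.iterations == 1

    def test_center_is_mean_of_members_at_convergence(self, rng):
        pts = rng.normal(size=(20, 2))
        res = lloyd(pts, baseline_init(pts, 3, "farthest_first"))
        for j in range(3):
            members = pts[res.labels == j]
            assert res.centers[j] == pytest.approx(members.mean(axis=0), abs=1e-9)
        d2 = ((pts - res.centers[res.labels]) ** 2).sum()
        assert res.inertia == pytest.approx(d2)


class TestGraphKMeans:
    def test_six_blob_recovery(self):
        spec = g.SyntheticSpec(m=36, n=1, k_true=6, noise_sd=0.2, seed=7)
        scores, labels, _ = g.generate_clustered_scores(spec)
        res = g.cluster_graph_kmeans(scores, 6)
        assert g.vmeasure(res.labels, labels) == pytest.approx(1.0)

    def test_repeated_runs_bit_identical(self):
        spec = g.SyntheticSpec(m=30, n=1, k_true=6, noise_sd=1.5, seed=11)
        scores, _, _ = g.generate_clustered_scores(spec)
        first = g.cluster_graph_kmeans(scores, 6)
        for _ in range(19):
            again = g.cluster_graph_kmeans(scores, 6)
            assert np.array_equal(again.labels, first.labels)
            assert np.array_equal(again.centers, first.centers)

    def test_random_init_unstable_on_noisy_data(self):
        spec = g.SyntheticSpec(m=30, n=1, k_true=6, noise_sd=2.0, seed=13)
        scores, _, _ = g.generate_clustered_scores(spec)
        pts = scores[:, None]
        partitions = set()
        for seed in range(20):
            C0 = baseline_init(pts, 6, "random", seed)
            partitions.add(tuple(lloyd(pts, C0).labels))
        assert len(partitions) > 1

    def test_estimator_api(self):
        pts, labels = two_blobs()
        km = g.GraphKMeans(n_clusters=2).fit(pts)
        assert g.vmeasure(km.labels_, labels) == pytest.approx(1.0)
        assert km.cluster_centers_.shape == (2, 1)
        assert km.predict(np.array([[0.01], [9.9]])).tolist() == sorted(
            set(km.labels_.tolist())
        )

    def test_agrees_with_reference_kmeans_inertia(self):
        # cross-check: sklearn's KMeans on an easy instance reaches the
        # same optimum the spectral seeding does
        from sklearn.cluster import KMeans

        pts, _ = two_blobs(sep=8.0, noise=0.3)
        ours = g.cluster_graph_kmeans(pts, 2)
        ref = KMeans(n_clusters=2, n_init=10, random_state=0).fit(pts)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-9)


class TestBaselineInit:
    def test_seeded_reproducibility(self, rng):
        pts = rng.normal(size=(12, 2))
        a = baseline_init(pts, 3, "random", 5)
        b = baseline_init(pts, 3, "random", 5)
        assert np.array_equal(a, b)

    def test_k_equals_m_selects_all_points(self, rng):
        pts = rng.normal(size=(5, 1))
        for strat in ("random", "kmeanspp", "farthest_first"):
            C = baseline_init(pts, 5, strat, 0)
            assert np.sort(C.ravel()) == pytest.approx(np.sort(pts.ravel()))

    def test_kmeanspp_seeds_both_blobs(self):
        pts, _ = two_blobs(sep=1000.0, noise=0.01)
        for seed in range(100):
            C = baseline_init(pts, 2, "kmeanspp", seed)
            assert (C < 500).sum() == 1 and (C > 500).sum() == 1

    def test_unknown_strategy(self):
        with pytest.raises(UnknownMethodError):
            baseline_init(np.zeros((3, 1)), 2, "quantum")

    def test_farthest_first_deterministic_ties_low_index(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        idx = _farthest_first(pts, 2)
        assert list(idx) == [1, 0]  # center point first, then lowest-index extreme
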