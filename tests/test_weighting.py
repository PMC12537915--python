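"""Objective weighting: dCor oracle agreement, hand values, contracts."""

import numpy as np
import pytest

import graphmcdm as g
from graphmcdm.errors import DegenerateWeightsError, ShapeMismatchError, \
    ValidationError
from graphmcdm.weighting import column_sd, information_content, criterion_stats
from conftest import make_matrix


def dcor_bruteforce(u, v):
    """Independent oracle: explicit double loops and explicit centering."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    m = len(u)
    a = np.empty((m, m))
    b = np.empty((m, m))
    for k in range(m):
        for l in range(m):
            a[k, l] = abs(u[k] - u[l])
            b[k, l] = abs(v[k] - v[l])
    A = np.empty((m, m))
    B = np.empty((m, m))
    for k in range(m):
        for l in range(m):
            A[k, l] = a[k, l] - a[k, :].mean() - a[:, l].mean() + a.mean()
            B[k, l] = b[k, l] - b[k, :].mean() - b[:, l].mean() + b.mean()
    dcov2 = sum(A[k, l] * B[k, l] for k in range(m) for l in range(m)) / m**2
    dvar_u = sum(A[k, l] ** 2 for k in range(m) for l in range(m)) / m**2
    dvar_v = sum(B[k, l] ** 2 for k in range(m) for l in range(m)) / m**2
    if dvar_u <= 0 or dvar_v <= 0:
        return 0.0
    return np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_u * dvar_v))


class TestColumnSd:
    def test_constant_and_closed_forms(self):
        V = np.array([[0.0, 0.0, 1.0], [0.0, 2.0, 2.0],
                      [0.0, 1.0, 3.0], [0.0, 1.0, 4.0]])
        sd = column_sd(V)
        assert sd[0] == 0.0
        assert sd[2] == pytest.approx(np.sqrt(5 / 3))

    def test_two_point_closed_form(self):
        assert column_sd(np.array([[0.0], [2.0]]))[0] == pytest.approx(np.sqrt(2))

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            column_sd(np.array([[1.0, 2.0]]))


class TestDistanceCorrelation:
    def test_self_correlation_is_one(self):
        v = np.array([0.3, 1.7, -2.0, 0.5])
        assert g.distance_correlation(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        v = np.array([0.0, 1.0, 2.0, 5.0])
        assert g.distance_correlation(v, 3.0 - 2.0 * v) == pytest.approx(1.0, abs=1e-12)

    def test_constant_argument_gives_zero(self):
        assert g.distance_correlation([1, 1, 1], [1, 2, 3]) == 0.0

    def test_quadratic_pair_matches_oracle(self):
        u = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([0.0, 1.0, 4.0, 9.0])
        assert g.distance_correlation(u, v) == pytest.approx(
            dcor_bruteforce(u, v), abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            g.distance_correlation([1, 2], [1, 2, 3])

    def test_agrees_with_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            m = int(rng.integers(3, 13))
            u, v = rng.normal(size=(2, m))
            assert g.distance_correlation(u, v) == pytest.approx(
                dcor_bruteforce(u, v), abs=1e-12
            )

    def test_always_in_unit_interval(self, rng):
        for _ in range(50):
            u, v = rng.standard_t(2, size=(2, 8))
            assert 0.0 <= g.distance_correlation(u, v) <= 1.0


class TestInformationContent:
    def test_single_criterion_is_zero(self):
        assert information_content([1.5], [[1.0]])[0] == 0.0

    def test_identical_columns_zero_information(self):
        V = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        stats = criterion_stats(V)
        assert stats.information == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_hand_value(self):
        DC = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert information_content([1.0, 2.0], DC) == pytest.approx([0.5, 1.0])


class TestDcritic:
    def test_mirror_columns_get_equal_weights(self):
        # same sd, symmetric dCor -> 0.5 / 0.5
        X = make_matrix(np.array([[1.0, 4.0], [2.0, 2.0], [4.0, 1.0]]))
        assert g.dcritic_weights(X).weights == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_composition_matches_step_oracle(self, rng):
        V = rng.uniform(0.1, 1.0, (5, 3))
        w = g.dcritic_weights(V).weights
        # independent composition of the four stages
        sd = V.std(axis=0, ddof=1)
        DC = np.array([[dcor_bruteforce(V[:, a], V[:, b]) for b in range(3)]
                       for a in range(3)])
        I = sd * (1 - DC).sum(axis=1)
        assert w == pytest.approx(I / I.sum(), abs=1e-12)

    def test_all_affine_columns_degenerate(self):
        V = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(DegenerateWeightsError):
            g.dcritic_weights(V)

    def test_duplicating_a_criterion_lowers_its_weight(self, rng):
        V = rng.uniform(0, 1, (8, 3))
        before = g.dcritic_weights(V).weights
        V2 = np.column_stack([V, V[:, 0]])
        after = g.dcritic_weights(V2).weights
        assert after[0] < before[0]
        assert after[0] == pytest.approx(after[3], abs=1e-12)


class TestEntropy:
    def test_uniform_column_zero_discrimination(self):
        V = np.array([[1.0, 1.0], [1.0, 3.0], [1.0, 5.0]])
        w = g.entropy_weights(V).weights
        assert w == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_hand_computed_weights(self):
        V = np.array([[2.0, 1.0], [1.0, 3.0], [1.0, 5.0]])
        p1 = np.array([0.5, 0.25, 0.25])
        p2 = np.array([1 / 9, 3 / 9, 5 / 9])
        e = [-(p * np.log(p)).sum() / np.log(3) for p in (p1, p2)]
        d = 1 - np.array(e)
        assert g.entropy_weights(V).weights == pytest.approx(d / d.sum(), abs=1e-12)

    def test_concentrated_column_dominates(self):
        V = np.array([[1.0, 1e-12], [1.0, 1e-12], [1.0, 1.0]])
        w = g.entropy_weights(V).weights
        assert w[1] > 0.99

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            g.entropy_weights(np.array([[-1.0, 2.0], [1.0, 2.0]]))


class TestMerec:
    def test_all_ones_degenerate_with_fallback(self):
        V = np.ones((3, 2))
        with pytest.raises(DegenerateWeightsError):
            g.merec_weights(V)
        w = g.merec_weights(V, uniform_fallback=True).weights
        assert w == pytest.approx([0.5, 0.5])

    def test_identical_columns_equal_weights(self):
        V = np.column_stack([[0.2, 0.5, 0.9], [0.2, 0.5, 0.9], [0.4, 0.3, 0.8]])
        w = g.merec_weights(V).weights
        assert w[0] == pytest.approx(w[1], abs=1e-12)

    def test_literal_transcription_oracle(self, rng):
        V = rng.uniform(0.05, 1.0, (4, 3))
        m, n = V.shape
        S = np.array([np.log(1 + np.mean([abs(np.log(V[i, j])) for j in range(n)]))
                      for i in range(m)])
        E = np.zeros(n)
        for j in range(n):
            for i in range(m):
                Sp = np.log(1 + sum(abs(np.log(V[i, jp])) for jp in range(n)
                                    if jp != j) / n)
                E[j] += abs(Sp - S[i])
        assert g.merec_weights(V).weights == pytest.approx(E / E.sum(), abs=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            g.merec_weights(np.array([[0.0, 0.5], [0.5, 0.5]]))


class TestWeightContracts:
    @pytest.mark.parametrize("method", ["dcritic", "entropy", "merec"])
    def test_sum_one_nonnegative_and_permutation_equivariant(self, rng, method):
        for _ in range(20):
            V = rng.uniform(0.05, 1.0, (9, 5))
            w = g.compute_weights(V, method).weights
            assert np.all(w >= 0)
            assert abs(w.sum() - 1.0) <= 1e-12
            perm = rng.permutation(5)
            wp = g.compute_weights(V[:, perm], method).weights
            assert wp == pytest.approx(w[perm], abs=1e-12)

    def test_estimator_interface(self, rng):
        V = rng.uniform(0.05, 1.0, (9, 4))
        est = g.DCRITICWeigher().fit(V)
        assert est.weights_ == pytest.approx(g.dcritic_weights(V).weights)
        assert est.dcor_.shape == (4, 4)
        assert np.allclose(est.dcor_, est.dcor_.T)
        assert np.allclose(np.diag(est.dcor_), 1.0)
        weighted = est.transform(V)
        assert weighted == pytest.approx(V * est.weights_)
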