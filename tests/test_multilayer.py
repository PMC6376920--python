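"""Supra-adjacency construction, walk counts, communicability, omega fit."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from winefp import (
    InterlayerWeights,
    LayerGraph,
    aggregate_layer,
    build_supra,
    communicability,
    communicability_matrix,
    count_walks,
    fit_omega,
)
from winefp.errors import DomainError, UsageError

NODES = ("w1", "w2")


def layer(name, A, nodes=NODES):
    return LayerGraph(name, nodes, np.asarray(A, dtype=float))


class TestBuildSupra:
    def test_single_layer_reduces_to_adjacency(self):
        A = [[0, 0.7], [0.7, 0]]
        supra = build_supra([layer("dna", A)], InterlayerWeights.scalar(1, 0.0))
        assert np.array_equal(supra.matrix, np.asarray(A))

    def test_zero_omega_is_block_diagonal(self):
        A1 = [[0, 1], [1, 0]]
        A2 = [[0, 0.5], [0.5, 0]]
        supra = build_supra(
            [layer("dna", A1), layer("chem", A2)], InterlayerWeights.scalar(2, 0.0)
        )
        assert np.array_equal(supra.matrix[:2, 2:], np.zeros((2, 2)))
        assert np.array_equal(supra.matrix[:2, :2], np.asarray(A1, dtype=float))
        assert np.array_equal(supra.matrix[2:, 2:], np.asarray(A2, dtype=float))

    def test_hand_constructed_two_layer_example(self):
        A1 = [[0, 1], [1, 0]]
        A2 = [[0, 0], [0, 0]]
        supra = build_supra(
            [layer("dna", A1), layer("chem", A2)], InterlayerWeights.scalar(2, 0.5)
        )
        expected = np.array(
            [
                [0, 1, 0.5, 0],
                [1, 0, 0, 0.5],
                [0.5, 0, 0, 0],
                [0, 0.5, 0, 0],
            ]
        )
        assert np.array_equal(supra.matrix, expected)

    def test_node_order_mismatch_rejected(self):
        a = layer("dna", [[0, 1], [1, 0]], nodes=("w1", "w2"))
        b = layer("chem", [[0, 1], [1, 0]], nodes=("w2", "w1"))
        with pytest.raises(UsageError):
            build_supra([a, b], InterlayerWeights.scalar(2, 0.1))

    def test_layer_invariants(self):
        with pytest.raises(UsageError):
            layer("bad", [[0, 1.5], [1.5, 0]])  # weight > 1
        with pytest.raises(UsageError):
            layer("bad", [[0.2, 0], [0, 0]])  # nonzero diagonal
        with pytest.raises(UsageError):
            InterlayerWeights(np.array([[0, 0.3], [0.6, 0]]))  # asymmetric


class TestWalks:
    def two_layer_supra(self):
        A1 = [[0, 1], [1, 0]]
        A2 = [[0, 0], [0, 0]]
        return build_supra(
            [layer("dna", A1), layer("chem", A2)], InterlayerWeights.scalar(2, 0.5)
        )

    def test_length_one_is_the_entry_itself(self):
        supra = self.two_layer_supra()
        p = supra.index("w1", "dna")
        q = supra.index("w2", "dna")
        assert count_walks(supra, 1, p, q) == 1.0

    def test_two_layer_length_two_self_walks(self):
        """From w1 in the DNA layer back to itself in two steps: via w2 in the
        same layer (1*1) and via its own copy in the other layer (0.5*0.5)."""
        supra = self.two_layer_supra()
        p = supra.index("w1", "dna")
        assert count_walks(supra, 2, p, p) == pytest.approx(1.25)

    def test_equals_exhaustive_enumeration_on_small_graphs(self):
        """(M^k)[p,q] == sum over all explicit vertex sequences, n<=5, k<=4."""
        rng = np.random.default_rng(0)
        for n in (2, 3, 4, 5):
            for _ in range(8):
                A = (rng.uniform(size=(n, n)) < 0.5).astype(float)
                A = np.triu(A, 1)
                A = A + A.T
                nodes = tuple(f"n{i}" for i in range(n))
                supra = build_supra(
                    [LayerGraph("g", nodes, A)], InterlayerWeights.scalar(1, 0.0)
                )
                for k in (1, 2, 3, 4):
                    p, q = int(rng.integers(n)), int(rng.integers(n))
                    brute = 0.0
                    for mids in itertools.product(range(n), repeat=k - 1):
                        seq = (p, *mids, q)
                        w = 1.0
                        for a, b in zip(seq, seq[1:]):
                            w *= A[a, b]
                        brute += w
                    assert count_walks(supra, k, p, q) == pytest.approx(brute)

    def test_invalid_length_rejected(self):
        supra = self.two_layer_supra()
        with pytest.raises(DomainError):
            count_walks(supra, 0, 0, 0)


class TestCommunicability:
    def test_zero_matrix_gives_identity(self):
        supra = build_supra(
            [layer("dna", [[0, 0], [0, 0]])], InterlayerWeights.scalar(1, 0.0)
        )
        assert communicability(supra, 0, 0) == pytest.approx(1.0)
        assert communicability(supra, 0, 1) == pytest.approx(0.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, size=(3, 3))
        A = np.triu(X, 1)
        A = A + A.T
        supra = build_supra(
            [LayerGraph("g", ("a", "b", "c"), A)], InterlayerWeights.scalar(1, 0.0)
        )
        E = communicability_matrix(supra)
        assert np.allclose(E, E.T)

    def test_matches_truncated_series(self):
        """exp(M)[p,q] == sum_{k<=20} M^k / k! within 1e-9 on a random matrix."""
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, size=(3, 3))
        A = np.triu(X, 1)
        A = A + A.T
        supra = build_supra(
            [LayerGraph("g", ("a", "b", "c"), A)], InterlayerWeights.scalar(1, 0.0)
        )
        series = np.eye(3)
        term = np.eye(3)
        for k in range(1, 21):
            term = term @ A / k
            series += term
        assert np.max(np.abs(communicability_matrix(supra) - series)) < 1e-9

    def test_monotone_in_edge_weight(self):
        base = np.array([[0, 0.2, 0.1], [0.2, 0, 0.3], [0.1, 0.3, 0]])
        bumped = base.copy()
        bumped[0, 1] = bumped[1, 0] = 0.4
        nodes = ("a", "b", "c")
        E0 = communicability_matrix(
            build_supra([LayerGraph("g", nodes, base)], InterlayerWeights.scalar(1, 0))
        )
        E1 = communicability_matrix(
            build_supra([LayerGraph("g", nodes, bumped)], InterlayerWeights.scalar(1, 0))
        )
        assert np.all(E1 >= E0 - 1e-12)


class TestAggregate:
    def three_node_layers(self):
        rng = np.random.default_rng(3)
        layers = []
        nodes = ("a", "b", "c")
        for name in ("dna", "chem"):
            X = rng.uniform(0, 1, size=(3, 3))
            A = np.triu(X, 1)
            A = A + A.T
            layers.append(LayerGraph(name, nodes, A))
        return layers

    def test_single_layer_reduces_to_offdiagonal_exponential(self):
        layers = self.three_node_layers()[:1]
        agg = aggregate_layer(layers, InterlayerWeights.scalar(1, 0.0))
        E = expm(layers[0].adjacency)
        expected = E.copy()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(agg, expected)

    def test_decoupled_layers_average_their_exponentials(self):
        """With omega = 0 cross-layer blocks vanish, so the copy-pair mean is
        sum_i exp(A_i) / h^2 off the diagonal."""
        layers = self.three_node_layers()
        agg = aggregate_layer(layers, InterlayerWeights.scalar(2, 0.0))
        expected = sum(expm(l.adjacency) for l in layers) / 4.0
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(agg, expected)

    def test_symmetric_with_zero_diagonal(self):
        layers = self.three_node_layers()
        agg = aggregate_layer(layers, InterlayerWeights.scalar(2, 0.3))
        assert np.allclose(agg, agg.T)
        assert np.all(np.diag(agg) == 0)


class TestFitOmega:
    def test_recovers_generating_scalar(self):
        layers = TestAggregate().three_node_layers()
        response = aggregate_layer(layers, InterlayerWeights.scalar(2, 0.5))
        weights, objective = fit_omega(layers, response, grid_step=0.1)
        assert weights.omega[0, 1] == pytest.approx(0.5)
        assert objective == pytest.approx(0.0, abs=1e-18)

    def test_objective_nonnegative_elsewhere(self):
        layers = TestAggregate().three_node_layers()
        response = aggregate_layer(layers, InterlayerWeights.scalar(2, 0.5))
        for value in (0.0, 0.2, 0.9):
            agg = aggregate_layer(layers, InterlayerWeights.scalar(2, value))
            assert np.sum((agg - response) ** 2) >= 0

    def test_single_layer_ties_resolve_to_zero(self):
        layers = TestAggregate().three_node_layers()[:1]
        response = aggregate_layer(layers, InterlayerWeights.scalar(1, 0.0))
        weights, objective = fit_omega(layers, response, grid_step=0.25)
        assert np.all(weights.omega == 0)
        assert objective == pytest.approx(0.0, abs=1e-18)

    def test_full_matrix_search_recovers_asymmetric_couplings(self):
        layers = TestAggregate().three_node_layers()
        W_true = InterlayerWeights(np.array([[0.0, 0.4], [0.4, 0.0]]))
        response = aggregate_layer(layers, W_true)
        weights, objective = fit_omega(
            layers, response, grid_step=0.2, full_matrix=True
        )
        assert weights.omega[0, 1] == pytest.approx(0.4)

    def test_dimension_mismatch_rejected(self):
        layers = TestAggregate().three_node_layers()
        with pytest.raises(UsageError):
            fit_omega(layers, np.zeros((2, 2)))
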