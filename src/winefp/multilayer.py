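"""Multiplex-network data integration over a common set of wines.

Each *layer* is a weighted undirected similarity graph over the same wines
(e.g. one layer from DNA-profile similarity, another from chemistry). The
multiplex couples the layers through their node copies: the supra-adjacency
matrix M carries the layer adjacencies A_1..A_h on its diagonal blocks and
ω_ij · I on the off-diagonal blocks, where the symmetric interlayer weight
ω_ij in [0, 1] measures the dependence between layers i and j.

Walk counts between node copies are entries of M^k; communicability weights
all walks by 1/k!, i.e. it is the matrix exponential exp(M) (including the
k = 0 identity term). The aggregate similarity between two wines collapses
their layer copies by averaging exp(M) over all copy pairs, and the
interlayer weights can be fitted by minimising the squared gap between the
aggregate and an observed response network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .errors import DomainError, UsageError


@dataclass
class LayerGraph:
    """One similarity layer: symmetric weights in [0, 1], zero diagonal."""

    layer_name: str
    nodes: Tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        A = np.asarray(self.adjacency, dtype=float)
        n = len(self.nodes)
        if A.shape != (n, n):
            raise UsageError(f"{self.layer_name}: adjacency shape {A.shape} != ({n},{n})")
        if not np.allclose(A, A.T):
            raise UsageError(f"{self.layer_name}: adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise UsageError(f"{self.layer_name}: diagonal must be zero")
        if np.any((A < 0) | (A > 1)):
            raise UsageError(f"{self.layer_name}: weights must lie in [0, 1]")
        self.adjacency = A


@dataclass
class InterlayerWeights:
    """Symmetric h x h matrix of interlayer coupling strengths in [0, 1]."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.omega, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise UsageError("omega must be square")
        if not np.allclose(W, W.T):
            raise UsageError("omega must be symmetric")
        if np.any(np.diag(W) != 0):
            raise UsageError("omega diagonal must be zero")
        if np.any((W < 0) | (W > 1)):
            raise UsageError("omega entries must lie in [0, 1]")
        self.omega = W

    @classmethod
    def scalar(cls, h: int, value: float) -> "InterlayerWeights":
        W = np.full((h, h), float(value))
        np.fill_diagonal(W, 0.0)
        return cls(W)


@dataclass
class SupraAdjacency:
    """Block matrix of the multiplex: A_i diagonal, omega_ij I off-diagonal."""

    matrix: np.ndarray
    layer_names: Tuple[str, ...]
    nodes: Tuple[str, ...]

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node: str, layer: str) -> int:
        """Flat index of a node copy (layer-major block layout)."""
        return self.layer_names.index(layer) * self.n_nodes + self.nodes.index(node)


def build_supra(layers: Sequence[LayerGraph], omega: InterlayerWeights) -> SupraAdjacency:
    """Assemble the supra-adjacency matrix from layers and interlayer weights."""
    if not layers:
        raise UsageError("build_supra needs at least one layer")
    nodes = layers[0].nodes
    for layer in layers[1:]:
        if layer.nodes != nodes:
            raise UsageError(
                f"layer {layer.layer_name}: node order differs from {layers[0].layer_name}"
            )
    h, n = len(layers), len(nodes)
    if omega.omega.shape != (h, h):
        raise UsageError(
            f"omega is {omega.omega.shape}, expected ({h}, {h}) for {h} layers"
        )
    M = np.zeros((h * n, h * n))
    eye = np.eye(n)
    for i in range(h):
        M[i * n : (i + 1) * n, i * n : (i + 1) * n] = layers[i].adjacency
        for j in range(h):
            if i != j:
                M[i * n : (i + 1) * n, j * n : (j + 1) * n] = omega.omega[i, j] * eye
    return SupraAdjacency(
        matrix=M, layer_names=tuple(l.layer_name for l in layers), nodes=nodes
    )


def count_walks(supra: SupraAdjacency, k: int, p: int, q: int) -> float:
    """Weighted number of length-k walks between node copies p and q: (M^k)[p,q]."""
    if k < 1:
        raise DomainError(f"walk length must be >= 1, got {k}")
    return float(np.linalg.matrix_power(supra.matrix, k)[p, q])


def communicability_matrix(supra: SupraAdjacency) -> np.ndarray:
    """exp(M): all-walk communicability between every pair of node copies."""
    return expm(supra.matrix)


def communicability(supra: SupraAdjacency, p: int, q: int) -> float:
    return float(communicability_matrix(supra)[p, q])


def aggregate_layer(
    layers: Sequence[LayerGraph], omega: InterlayerWeights
) -> np.ndarray:
    """Aggregate wine-by-wine similarity: mean communicability over copy pairs.

    agg(p, q) = mean over layer pairs (i, j) of exp(M)[p_i, q_j] for p != q;
    the diagonal is set to zero (self-similarity is not informative here).
    """
    supra = build_supra(layers, omega)
    E = communicability_matrix(supra)
    h, n = supra.n_layers, supra.n_nodes
    blocks = E.reshape(h, n, h, n)
    agg = blocks.mean(axis=(0, 2))
    agg = 0.5 * (agg + agg.T)
    np.fill_diagonal(agg, 0.0)
    return agg


def fit_omega(
    layers: Sequence[LayerGraph],
    response: np.ndarray,
    grid_step: float = 0.1,
    full_matrix: bool = False,
) -> Tuple[InterlayerWeights, float]:
    """Grid-search interlayer weights minimising the gap to a response network.

    The objective is sum over unordered wine pairs of
    (aggregate(p, q) - response(p, q))^2. By default a single shared scalar
    ω is searched over {0, step, ..., 1}; ties resolve to the smallest ω.
    ``full_matrix=True`` searches every upper-triangle entry independently
    and is restricted to h <= 4 layers (the grid grows exponentially).
    """
    if not (0 < grid_step <= 0.5):
        raise UsageError(f"grid_step must be in (0, 0.5], got {grid_step}")
    h = len(layers)
    n = len(layers[0].nodes)
    response = np.asarray(response, dtype=float)
    if response.shape != (n, n):
        raise UsageError(f"response shape {response.shape} != ({n}, {n})")
    if not np.allclose(response, response.T):
        raise UsageError("response matrix must be symmetric")
    iu = np.triu_indices(n, k=1)

    def objective(weights: InterlayerWeights) -> float:
        agg = aggregate_layer(layers, weights)
        diff = agg[iu] - response[iu]
        return float(diff @ diff)

    grid = np.arange(0.0, 1.0 + 1e-9, grid_step)
    if not full_matrix:
        best: Optional[Tuple[float, InterlayerWeights]] = None
        for value in grid:
            W = InterlayerWeights.scalar(h, value)
            obj = objective(W)
            if best is None or obj < best[0] - 1e-15:
                best = (obj, W)
        assert best is not None
        return best[1], best[0]

    if h > 4:
        raise UsageError("full-matrix omega search is limited to 4 layers")
    pairs = list(itertools.combinations(range(h), 2))
    best = None
    for combo in itertools.product(grid, repeat=len(pairs)):
        W = np.zeros((h, h))
        for (i, j), value in zip(pairs, combo):
            W[i, j] = W[j, i] = value
        weights = InterlayerWeights(W)
        obj = objective(weights)
        if best is None or obj < best[0] - 1e-15:
            best = (obj, weights)
    assert best is not None
    return best[1], best[0]


def layer_from_distance(name: str, labels: Sequence[str], distances: np.ndarray) -> LayerGraph:
    """Convenience: turn a distance matrix in [0,1] into a similarity layer."""
    A = 1.0 - np.asarray(distances, dtype=float)
    np.fill_diagonal(A, 0.0)
    return LayerGraph(layer_name=name, nodes=tuple(labels), adjacency=A)
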