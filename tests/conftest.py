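import numpy as np
import pytest

from winefp import (
    BlendSpec,
    Dataset,
    DropoutModel,
    Locus,
    Panel,
    VarietyGenotype,
    WineProfile,
    default_panel,
    simulate_frequency_panel,
    simulate_variety,
)
from winefp.distance import DistanceMatrix


@pytest.fixture
def panel():
    return default_panel()


@pytest.fixture
def small_panel():
    return Panel(
        [
            Locus("VVS2", 2, 110, 180),
            Locus("VVMD27", 2, 160, 230),
            Locus("VrZag79", 2, 230, 300),
        ]
    )


@pytest.fixture
def spectra(panel):
    return simulate_frequency_panel(panel, n_alleles_per_locus=8, seed=11)


@pytest.fixture
def varieties(spectra):
    return [simulate_variety(spectra, f"V{k}", seed=100 + k) for k in range(4)]


@pytest.fixture
def dropout_defaults():
    return DropoutModel()


def make_distance_matrix(labels, values):
    """DistanceMatrix from a plain array, marking everything comparable."""
    values = np.asarray(values, dtype=float)
    n = len(labels)
    return DistanceMatrix(
        list(labels),
        values,
        np.ones((n, n), dtype=bool),
        np.full((n, n), 9, dtype=int),
    )


def random_additive_tree(n, rng):
    """Random unrooted binary tree; returns (labels, additive distance matrix).

    Distances are scaled into [0, 1] so they satisfy the DistanceMatrix
    contract; scaling preserves additivity.
    """
    adj = {}

    def add_edge(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    active = [f"T{i:02d}" for i in range(n)]
    labels = list(active)
    nxt = 0
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        new = f"I{nxt}"
        nxt += 1
        add_edge(a, new, rng.uniform(0.1, 1.0))
        add_edge(b, new, rng.uniform(0.1, 1.0))
        active = [x for x in active if x not in (a, b)] + [new]
    center = f"I{nxt}"
    for x in active:
        add_edge(x, center, rng.uniform(0.1, 1.0))

    D = np.zeros((n, n))
    for si, s in enumerate(labels):
        seen = {s: 0.0}
        stack = [s]
        while stack:
            cur = stack.pop()
            for nb, w in adj[cur]:
                if nb not in seen:
                    seen[nb] = seen[cur] + w
                    stack.append(nb)
        for ti, t in enumerate(labels):
            D[si, ti] = seen[t]
    return labels, D / D.max()


def tiny_dataset(panel):
    """Two diploid references and one wine over the first loci of *panel*."""
    loci = panel.names
    v1 = VarietyGenotype("Sangiovese", {loci[i]: (150 + 2 * i, 154 + 2 * i) for i in range(6)})
    v2 = VarietyGenotype("Merlot", {loci[i]: (152 + 2 * i, 156 + 2 * i) for i in range(6)})
    wine = WineProfile("Brunello", {loci[i]: frozenset({150 + 2 * i, 154 + 2 * i}) for i in range(6)})
    return Dataset(panel=panel, varieties=[v1, v2], wines=[wine])
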