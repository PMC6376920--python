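"""Tree building and cluster confidence for fingerprint distance matrices.

Two tree builders are provided:

* :func:`neighbor_joining` — the classical Saitou-Nei agglomeration on the
  Q-criterion, exact on additive distances; ties broken lexicographically
  by the smallest leaf label in each subtree so results are deterministic.
* :func:`average_linkage` — UPGMA-style dendrogram with arithmetic-average
  distance updates and ultrametric heights (merge height = distance / 2).

Cluster confidence uses multiscale bootstrap over *loci* (the resampling
unit available to an SSR panel): at each scale r a resample of
m = round(r * L) loci is drawn with replacement, the tree is rebuilt, and
each original cluster's recurrence frequency (BP) is recorded. Fitting

    z_r = v * sqrt(r) + c / sqrt(r),      z_r = Phi^-1(1 - BP_r)

by weighted least squares yields the signed distance v and curvature c of
the multiscale model, and the approximately unbiased p-value
AU = 1 - Phi(v - c). BP at scale 1 is the plain bootstrap probability,
which is biased; AU corrects the bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import norm

from .distance import (
    DEFAULT_MIN_COTYPED,
    DistanceMatrix,
    matrix_from_locus_counts,
    similarity_tensors,
)
from .errors import DegenerateFitError, UsageError
from .model import Dataset
from .tree import Tree, TreeNode

log = logging.getLogger(__name__)

DEFAULT_SCALES: Tuple[float, ...] = tuple(round(0.5 + 0.1 * k, 1) for k in range(10))
DEFAULT_N_BOOT = 1000


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Classical Saitou-Nei NJ; returns an unrooted tree (trifurcating root).

    At each step the pair (i, j) minimising
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` is joined;
    pendant lengths follow the standard two-point formulas, with negative
    estimates clamped to zero (and logged). Ties on Q are broken by the
    lexicographically smallest (label_i, label_j) pair, where an internal
    node inherits the smallest leaf label of its subtree.
    """
    n = len(d.labels)
    if n < 3:
        raise UsageError("neighbor_joining needs at least 3 taxa")
    D = d.values.copy()
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in d.labels]
    keys: List[str] = list(d.labels)  # tie-break key per active node
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (m - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: Optional[Tuple[str, str, int, int]] = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    ka, kb = keys[active[a]], keys[active[b]]
                    pair = (min(ka, kb), max(ka, kb))
                    if best is None or pair < best[:2]:
                        best = (*pair, a, b)
        assert best is not None
        a, b = best[2], best[3]
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (row_sums[a] - row_sums[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li), _clamp(lj)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = sorted(
            [nodes[i], nodes[j]], key=lambda nd: min(nd.leaf_names())
        )
        # Distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # Resolve the final three nodes around a trifurcating root.
    i, j, k = active
    li = _clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = _clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = _clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = length
    root = TreeNode()
    root.children = sorted(
        [nodes[i], nodes[j], nodes[k]], key=lambda nd: min(nd.leaf_names())
    )
    return Tree(root, rooted=False)


def _clamp(x: float) -> float:
    if x < 0:
        if x < -1e-12:
            log.info("negative branch length %.3g clamped to 0", x)
        return 0.0
    return x


# ---------------------------------------------------------------------------
# Average-linkage dendrogram (UPGMA)
# ---------------------------------------------------------------------------

def average_linkage(d: DistanceMatrix) -> Tree:
    """UPGMA dendrogram: ultrametric heights, size-weighted average update."""
    n = len(d.labels)
    if n < 2:
        raise UsageError("average_linkage needs at least 2 taxa")
    D = d.values.astype(float).copy()
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in d.labels]
    heights = [0.0] * n
    sizes = [1] * n
    keys = list(d.labels)
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = D[i, j]
                ka, kb = keys[i], keys[j]
                pair = (min(ka, kb), max(ka, kb))
                cand = (dij, pair, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dij, _, i, j = best
        height = dij / 2.0
        parent = TreeNode()
        nodes[i].length = max(height - heights[i], 0.0)
        nodes[j].length = max(height - heights[j], 0.0)
        parent.children = sorted(
            [nodes[i], nodes[j]], key=lambda nd: min(nd.leaf_names())
        )
        new_size = sizes[i] + sizes[j]
        new_row = (sizes[i] * D[i, :] + sizes[j] * D[j, :]) / new_size
        D = np.vstack([D, new_row])
        D = np.column_stack([D, np.append(new_row, 0.0)])
        nodes.append(parent)
        heights.append(height)
        sizes.append(new_size)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    return Tree(nodes[active[0]], rooted=True)


def to_newick(t: Tree) -> str:
    return t.to_newick()


# ---------------------------------------------------------------------------
# Multiscale bootstrap
# ---------------------------------------------------------------------------

@dataclass
class ClusterSupport:
    """Bootstrap evidence for one cluster of the original tree."""

    cluster: FrozenSet[str]
    bp: float = float("nan")  # bootstrap probability at the scale closest to 1
    au: float = float("nan")  # approximately unbiased p-value
    v: float = float("nan")  # signed distance
    c: float = float("nan")  # curvature
    bp_by_scale: Dict[float, float] = field(default_factory=dict)
    n_boot: int = 0


def _clusters_of(tree: Tree, method: str) -> Set[FrozenSet[str]]:
    return tree.bipartitions() if method == "nj" else tree.clades()


def _build_tree(dm: DistanceMatrix, method: str) -> Tree:
    return neighbor_joining(dm) if method == "nj" else average_linkage(dm)


def multiscale_bootstrap(
    dataset: Dataset,
    method: str = "nj",
    scales: Sequence[float] = DEFAULT_SCALES,
    n_boot: int = DEFAULT_N_BOOT,
    min_cotyped: int = DEFAULT_MIN_COTYPED,
    seed: int = 0,
    metric: str = "dice",
) -> List[ClusterSupport]:
    """BP curves over scales for every cluster of the original tree.

    The resampling unit is the locus: at scale r, each replicate draws
    round(r * L) loci with replacement and rebuilds distances and the tree.
    The comparability threshold is scaled with r (max(1, round(r *
    min_cotyped))) so shrunken panels are not uniformly incomparable.
    AU/v/c are filled in by :func:`au_from_bp`.
    """
    if method not in ("nj", "average"):
        raise UsageError(f"unknown clustering method {method!r}")
    if n_boot < 1:
        raise UsageError("n_boot must be >= 1")
    loci = dataset.panel.names
    L = len(loci)
    if L < 2:
        raise UsageError("multiscale bootstrap needs a panel with >= 2 loci")
    scales = [float(r) for r in scales]
    if any(round(r * L) < 1 for r in scales):
        raise UsageError("a scale yields an empty locus resample")

    profiles = list(dataset.varieties) + list(dataset.wines)
    labels = [p.variety_id if hasattr(p, "variety_id") else p.wine_id for p in profiles]
    S, T = similarity_tensors(profiles, loci, metric)
    base_counts = np.ones(L)
    base_dm = matrix_from_locus_counts(S, T, base_counts, labels, min_cotyped)
    original = _build_tree(base_dm, method)
    clusters = sorted(_clusters_of(original, method), key=lambda c: (len(c), sorted(c)))
    if not clusters:
        return []

    rng = np.random.default_rng(seed)
    hits = {r: {cl: 0 for cl in clusters} for r in scales}
    for r in scales:
        m = int(round(r * L))
        thresh = max(1, int(round(r * min_cotyped)))
        for _ in range(n_boot):
            idx = rng.integers(0, L, size=m)
            counts = np.bincount(idx, minlength=L)
            dm = matrix_from_locus_counts(S, T, counts, labels, thresh)
            boot_clusters = _clusters_of(_build_tree(dm, method), method)
            for cl in clusters:
                if cl in boot_clusters:
                    hits[r][cl] += 1

    ref_scale = min(scales, key=lambda r: abs(r - 1.0))
    supports = []
    for cl in clusters:
        bp_by_scale = {r: hits[r][cl] / n_boot for r in scales}
        support = ClusterSupport(
            cluster=cl, bp=bp_by_scale[ref_scale], bp_by_scale=bp_by_scale, n_boot=n_boot
        )
        supports.append(au_from_bp(support))
    return supports


def _fit_msboot(
    scales: np.ndarray, bp: np.ndarray, n_boot: int
) -> Tuple[float, float, np.ndarray]:
    """WLS fit of z_r = v sqrt(r) + c / sqrt(r); returns (v, c, covariance).

    Weights are the binomial delta-method weights
    n_boot * phi(z_r)^2 / (bp_r (1 - bp_r)).
    """
    z = norm.ppf(1.0 - bp)
    w = n_boot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, WX.T @ z)
    cov = np.linalg.inv(xtwx)
    return float(beta[0]), float(beta[1]), cov


def au_from_bp(support: ClusterSupport) -> ClusterSupport:
    """Fill au, v, c from the recorded BP-by-scale curve.

    Degenerate curves fall back to the limits: all-zero BP means the cluster
    never reappears (au = 0); all-one BP means it always does (au = 1).
    Otherwise at least two scales with BP strictly inside (0, 1) are needed.
    """
    if not support.bp_by_scale:
        raise DegenerateFitError("no bootstrap curve recorded")
    items = sorted(support.bp_by_scale.items())
    scales = np.array([r for r, _ in items])
    bp = np.array([b for _, b in items])
    usable = (bp > 0.0) & (bp < 1.0)
    if np.all(bp == 0.0):
        support.au, support.v, support.c = 0.0, float("inf"), 0.0
        return support
    if np.all(bp == 1.0):
        support.au, support.v, support.c = 1.0, float("-inf"), 0.0
        return support
    if np.unique(scales[usable]).size < 2:
        raise DegenerateFitError(
            f"cluster {sorted(support.cluster)}: fewer than 2 usable scales"
        )
    v, c, _ = _fit_msboot(scales[usable], bp[usable], max(support.n_boot, 1))
    support.v, support.c = v, c
    support.au = float(1.0 - norm.cdf(v - c))
    return support
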