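"""A minimal phylogenetic tree container with Newick export.

Neighbor-Joining output is unrooted; it is stored here with an arbitrary
trifurcating root. Dendrograms from agglomerative clustering are rooted and
binary. Branch lengths are non-negative (clamped upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Set, Tuple

import numpy as np

from .errors import UsageError


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0  # branch length to parent
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.walk() if n.is_leaf]


@dataclass
class Tree:
    root: TreeNode
    rooted: bool = False

    def __post_init__(self) -> None:
        names = self.root.leaf_names()
        if len(set(names)) != len(names):
            raise UsageError("leaf labels must be unique")
        if any(n is None for n in names):
            raise UsageError("every leaf must be labelled")

    @property
    def leaves(self) -> List[str]:
        return self.root.leaf_names()

    # -- topology ----------------------------------------------------------

    def clades(self) -> Set[FrozenSet[str]]:
        """Leaf sets of all internal nodes below the root (rooted reading)."""
        out: Set[FrozenSet[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            out.add(frozenset(node.leaf_names()))
        return out

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Non-trivial splits induced by internal edges (unrooted reading).

        Each split is canonicalised as the side *not* containing the
        lexicographically smallest leaf, so the representation does not
        depend on rooting.
        """
        all_leaves = frozenset(self.leaves)
        anchor = min(all_leaves)
        out: Set[FrozenSet[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    # -- metrics -----------------------------------------------------------

    def leaf_distance_matrix(self) -> Tuple[List[str], np.ndarray]:
        """Pairwise path lengths between leaves (sum of branch lengths)."""
        # Build an undirected adjacency over node objects.
        adj: Dict[int, List[Tuple[int, float]]] = {}
        nodes: Dict[int, TreeNode] = {}
        for node in self.root.walk():
            nodes[id(node)] = node
            adj.setdefault(id(node), [])
            for child in node.children:
                adj.setdefault(id(child), [])
                adj[id(node)].append((id(child), child.length))
                adj[id(child)].append((id(node), child.length))
        leaves = [nid for nid, n in nodes.items() if n.is_leaf]
        labels = sorted(nodes[nid].name for nid in leaves)
        index = {lab: k for k, lab in enumerate(labels)}
        dist = np.zeros((len(labels), len(labels)))
        for start in leaves:
            # Dijkstra is overkill on a tree: simple DFS accumulation.
            seen = {start: 0.0}
            stack = [start]
            while stack:
                cur = stack.pop()
                for nxt, w in adj[cur]:
                    if nxt not in seen:
                        seen[nxt] = seen[cur] + w
                        stack.append(nxt)
            i = index[nodes[start].name]
            for other in leaves:
                j = index[nodes[other].name]
                dist[i, j] = seen[other]
        return labels, dist

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        """Newick with branch lengths at 6 decimals; labels quoted if needed."""
        return _newick_node(self.root, top=True) + ";"


def _quote(label: str) -> str:
    if any(c in label for c in " \t(),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: TreeNode, top: bool = False) -> str:
    if node.is_leaf:
        body = _quote(node.name)
    else:
        body = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
        if node.name:
            body += _quote(node.name)
    if top:
        return body
    return f"{body}:{node.length:.6f}"
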