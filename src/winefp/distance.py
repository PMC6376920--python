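"""Allele-sharing distances between fingerprints.

Profiles are compared locus by locus on their allele *sets* (a diploid
reference contributes one or two distinct sizes; a blended wine may carry
more). Per-locus similarity is the Dice coefficient

    s(a, b) = 2 |a ∩ b| / (|a| + |b|)

which, for two heterozygous diploid genotypes, reduces to the classical
proportion-of-shared-alleles similarity. The distance between two profiles
is one minus the mean similarity over loci typed in both.

Pairs sharing fewer than ``min_cotyped`` typed loci are genetically
incomparable: their distance is pinned to the maximum 1.0 and flagged, so
downstream tree building still receives a complete matrix while reports can
carry the comparability mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .errors import DomainError, UsageError
from .model import VarietyGenotype, WineProfile

Profile = Union[VarietyGenotype, WineProfile]

#: Minimum co-typed loci for a comparable pair. Panels run 7-10 loci and
#: monovarietal work tolerates slightly fewer; 4 keeps the comparison
#: meaningfully multi-locus.
DEFAULT_MIN_COTYPED = 4


def profile_id(p: Profile) -> str:
    return p.variety_id if isinstance(p, VarietyGenotype) else p.wine_id


def allele_sets(p: Profile) -> Dict[str, frozenset]:
    """Locus -> distinct allele sizes, for either profile kind."""
    return {locus: p.allele_set(locus) for locus in p.calls}


def locus_similarity(a: frozenset, b: frozenset, metric: str = "dice") -> float:
    """Similarity of two allele sets at one locus, in [0, 1]."""
    if not a or not b:
        raise DomainError("locus_similarity needs non-empty allele sets")
    inter = len(a & b)
    if metric == "dice":
        return 2.0 * inter / (len(a) + len(b))
    if metric == "jaccard":
        return inter / len(a | b)
    raise UsageError(f"unknown metric {metric!r}")


def profile_distance(
    pa: Profile,
    pb: Profile,
    min_cotyped: int = DEFAULT_MIN_COTYPED,
    metric: str = "dice",
) -> Tuple[float, bool, int]:
    """(distance, comparable flag, number of co-typed loci) for one pair."""
    sa, sb = allele_sets(pa), allele_sets(pb)
    shared = sorted(set(sa) & set(sb))
    n_cotyped = len(shared)
    if n_cotyped < min_cotyped:
        return 1.0, False, n_cotyped
    mean_sim = sum(locus_similarity(sa[l], sb[l], metric) for l in shared) / n_cotyped
    return 1.0 - mean_sim, True, n_cotyped


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with comparability metadata."""

    labels: List[str]
    values: np.ndarray
    comparable: np.ndarray
    n_cotyped: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        self.comparable = np.asarray(self.comparable, dtype=bool)
        self.n_cotyped = np.asarray(self.n_cotyped, dtype=int)
        if self.values.shape != (n, n):
            raise UsageError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise UsageError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise UsageError("distance matrix must have zero diagonal")
        if np.any((self.values < 0) | (self.values > 1)):
            raise UsageError("distances must lie in [0, 1]")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(
            list(labels),
            self.values[np.ix_(idx, idx)],
            self.comparable[np.ix_(idx, idx)],
            self.n_cotyped[np.ix_(idx, idx)],
        )


def distance_matrix(
    profiles: Sequence[Profile],
    min_cotyped: int = DEFAULT_MIN_COTYPED,
    metric: str = "dice",
) -> DistanceMatrix:
    """All-pairs allele-sharing distances for a list of profiles."""
    if len(profiles) < 2:
        raise UsageError("distance_matrix needs at least 2 profiles")
    labels = [profile_id(p) for p in profiles]
    if len(set(labels)) != len(labels):
        raise UsageError("duplicate profile ids")
    n = len(profiles)
    values = np.zeros((n, n))
    comparable = np.eye(n, dtype=bool)
    cotyped = np.zeros((n, n), dtype=int)
    for i in range(n):
        cotyped[i, i] = len(profiles[i].calls)
        for j in range(i + 1, n):
            d, comp, k = profile_distance(profiles[i], profiles[j], min_cotyped, metric)
            values[i, j] = values[j, i] = d
            comparable[i, j] = comparable[j, i] = comp
            cotyped[i, j] = cotyped[j, i] = k
    return DistanceMatrix(labels, values, comparable, cotyped)


# ---------------------------------------------------------------------------
# Locus-resolved similarity tensors (used by the locus bootstrap)
# ---------------------------------------------------------------------------

def similarity_tensors(
    profiles: Sequence[Profile], loci: Sequence[str], metric: str = "dice"
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-locus pairwise similarity S and co-typed indicator T.

    Returns arrays of shape (L, n, n): ``T[l, i, j]`` is 1 where locus l is
    typed in both profiles, and ``S[l, i, j]`` the locus similarity there
    (0 elsewhere). Resampling loci then reduces to weighted averages of
    these tensors, which keeps the bootstrap inner loop cheap.
    """
    n = len(profiles)
    sets = [allele_sets(p) for p in profiles]
    L = len(loci)
    S = np.zeros((L, n, n))
    T = np.zeros((L, n, n))
    for l, locus in enumerate(loci):
        for i in range(n):
            if locus not in sets[i]:
                continue
            for j in range(i, n):
                if locus not in sets[j]:
                    continue
                s = locus_similarity(sets[i][locus], sets[j][locus], metric)
                S[l, i, j] = S[l, j, i] = s
                T[l, i, j] = T[l, j, i] = 1.0
    return S, T


def matrix_from_locus_counts(
    S: np.ndarray,
    T: np.ndarray,
    counts: np.ndarray,
    labels: Sequence[str],
    min_cotyped: int,
) -> DistanceMatrix:
    """Distance matrix for a weighted multiset of loci (bootstrap replicate)."""
    w = counts.astype(float)
    cot = np.tensordot(w, T, axes=1)
    sim = np.tensordot(w, S, axes=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_sim = np.where(cot > 0, sim / np.where(cot > 0, cot, 1.0), 0.0)
    comparable = cot >= min_cotyped
    values = np.where(comparable, 1.0 - mean_sim, 1.0)
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(comparable, True)
    values = 0.5 * (values + values.T)
    return DistanceMatrix(list(labels), values, comparable, cot.astype(int))
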