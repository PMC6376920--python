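"""Candidate-variety assessment for blended wines.

A wine fingerprint is a union of validated allele sets; a candidate variety
is *compatible* with the blend when (nearly) all of its allele copies show
up in the wine. The **inclusion score** quantifies this: over the loci
typed in both profiles, it is the fraction of candidate allele copies
(homozygotes weigh 2) found in the wine's allele set. The score is a
deterministic degraded-DNA tolerant statistic, not a calibrated
probability: a threshold θ = 0.75 tolerates roughly one dropped allele copy
per two loci on a seven-locus comparison.

The score is deliberately asymmetric: foreign alleles in the wine (other
blend components, drop-ins) do not lower the inclusion of a candidate —
they only affect the allele-sharing *distance*, which is reported alongside
and drives the main-variety assignment. Assignments whose winning margin is
below ε are flagged ambiguous, the behaviour wanted for pairs of varieties
that are nearly indistinguishable on a small SSR panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA

from .distance import DEFAULT_MIN_COTYPED, Profile, allele_sets, profile_distance, profile_id
from .errors import UsageError
from .model import VarietyGenotype, WineProfile

DEFAULT_THETA = 0.75
DEFAULT_EPSILON = 0.02


@dataclass(frozen=True)
class CandidateAssessment:
    wine_id: str
    variety_id: str
    inclusion_score: float
    distance: float
    n_cotyped: int
    presence_call: str  # compatible | excluded | inconclusive


@dataclass(frozen=True)
class Assignment:
    """Main varietal component call: assigned, ambiguous, or no_call."""

    variety_id: Optional[str]
    margin: Optional[float]
    status: str


def inclusion_score(
    wine: WineProfile, candidate: VarietyGenotype, min_cotyped: int = DEFAULT_MIN_COTYPED
) -> Tuple[float, int]:
    """(score, n_cotyped): fraction of candidate allele copies present in the wine."""
    shared = sorted(set(wine.calls) & set(candidate.calls))
    if not shared:
        return 0.0, 0
    matched = 0
    for locus in shared:
        wine_alleles = wine.calls[locus]
        for allele in candidate.calls[locus]:  # two copies, possibly equal
            if allele in wine_alleles:
                matched += 1
    return matched / (2 * len(shared)), len(shared)


def assess_candidates(
    wine: WineProfile,
    candidates: Sequence[VarietyGenotype],
    theta: float = DEFAULT_THETA,
    min_cotyped: int = DEFAULT_MIN_COTYPED,
) -> List[CandidateAssessment]:
    """Score every candidate and call presence/absence.

    Results are sorted by ascending distance, ties by descending score,
    then label — so the most plausible blend component comes first.
    """
    if not candidates:
        raise UsageError("assess_candidates needs at least one candidate")
    out = []
    for cand in candidates:
        score, n_cotyped = inclusion_score(wine, cand, min_cotyped)
        dist, comparable, _ = profile_distance(wine, cand, min_cotyped)
        if n_cotyped < min_cotyped:
            call = "inconclusive"
        elif score >= theta:
            call = "compatible"
        else:
            call = "excluded"
        out.append(
            CandidateAssessment(
                wine_id=wine.wine_id,
                variety_id=cand.variety_id,
                inclusion_score=score,
                distance=dist,
                n_cotyped=n_cotyped,
                presence_call=call,
            )
        )
    out.sort(key=lambda a: (a.distance, -a.inclusion_score, a.variety_id))
    return out


def assign_main_variety(
    assessments: Sequence[CandidateAssessment], epsilon: float = DEFAULT_EPSILON
) -> Assignment:
    """Pick the main varietal component: smallest distance among comparable calls."""
    comparable = [a for a in assessments if a.presence_call != "inconclusive"]
    if not comparable:
        return Assignment(variety_id=None, margin=None, status="no_call")
    ranked = sorted(comparable, key=lambda a: (a.distance, -a.inclusion_score, a.variety_id))
    best = ranked[0]
    if len(ranked) == 1:
        return Assignment(variety_id=best.variety_id, margin=None, status="assigned")
    margin = ranked[1].distance - best.distance
    status = "ambiguous" if margin < epsilon else "assigned"
    return Assignment(variety_id=best.variety_id, margin=margin, status=status)


# ---------------------------------------------------------------------------
# Ordination (PCA on the allele incidence matrix)
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    labels: List[str]
    coordinates: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    feature_names: List[str] = field(default_factory=list)


def ordinate(profiles: Sequence[Profile], n_components: int = 2) -> OrdinationResult:
    """PCA of the binary (locus, allele) incidence matrix.

    Each profile becomes a 0/1 vector over every (locus, allele) pair
    observed anywhere in the input; columns are mean-centred and projected
    on the leading principal axes. Untyped loci simply contribute zeros —
    presence/absence is the only information a wine's allele set carries.
    """
    if len(profiles) < 2:
        raise UsageError("ordinate needs at least 2 profiles")
    labels = [profile_id(p) for p in profiles]
    sets = [allele_sets(p) for p in profiles]
    features = sorted({(loc, a) for s in sets for loc, alleles in s.items() for a in alleles})
    X = np.zeros((len(profiles), len(features)))
    feat_index = {f: k for k, f in enumerate(features)}
    for i, s in enumerate(sets):
        for loc, alleles in s.items():
            for a in alleles:
                X[i, feat_index[(loc, a)]] = 1.0
    k = min(n_components, len(profiles) - 1, len(features))
    centred = X - X.mean(axis=0)
    total_var = (centred**2).sum()
    if total_var == 0 or k < 1:
        # All profiles identical: nothing to ordinate.
        k = max(k, 1)
        return OrdinationResult(
            labels=labels,
            coordinates=np.zeros((len(profiles), k)),
            explained_variance_ratio=np.zeros(k),
            feature_names=[f"{loc}:{a}" for loc, a in features],
        )
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    return OrdinationResult(
        labels=labels,
        coordinates=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_names=[f"{loc}:{a}" for loc, a in features],
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def admixture_report(
    wine: WineProfile,
    assessments: Sequence[CandidateAssessment],
    assignment: Assignment,
    newick: Optional[str] = None,
    supports: Optional[Sequence] = None,
    ordination: Optional[OrdinationResult] = None,
    cumulative_pi: Optional[float] = None,
) -> Dict:
    """Assemble the per-wine JSON report document."""
    for a in assessments:
        if a.wine_id != wine.wine_id:
            raise UsageError(
                f"assessment for {a.wine_id} mixed into report for {wine.wine_id}"
            )
    doc: Dict = {
        "wine_id": wine.wine_id,
        "profile": {loc: sorted(wine.calls[loc]) for loc in sorted(wine.calls)},
        "candidates": [
            {
                "variety_id": a.variety_id,
                "inclusion_score": round(a.inclusion_score, 6),
                "distance": round(a.distance, 6),
                "n_cotyped": a.n_cotyped,
                "presence_call": a.presence_call,
            }
            for a in assessments
        ],
        "assignment": {
            "variety_id": assignment.variety_id,
            "margin": None if assignment.margin is None else round(assignment.margin, 6),
            "status": assignment.status,
        },
    }
    if newick is not None:
        doc["newick"] = newick
    if supports is not None:
        doc["cluster_support"] = [
            {
                "cluster": sorted(s.cluster),
                "bp": round(s.bp, 4),
                "au": None if np.isnan(s.au) else round(s.au, 4),
                "v": None if np.isnan(s.v) else round(s.v, 4),
                "c": None if np.isnan(s.c) else round(s.c, 4),
            }
            for s in supports
        ]
    if ordination is not None:
        doc["ordination"] = {
            "labels": ordination.labels,
            "coordinates": [[round(x, 6) for x in row] for row in ordination.coordinates],
            "explained_variance_ratio": [
                round(float(x), 6) for x in ordination.explained_variance_ratio
            ],
        }
    if cumulative_pi is not None:
        doc["panel_cumulative_pi"] = cumulative_pi
    return doc


def report_to_json(doc: Dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True)


def report_summary(doc: Dict) -> str:
    """Human-readable digest of an admixture report."""
    lines = [f"Wine {doc['wine_id']}"]
    assignment = doc["assignment"]
    if assignment["variety_id"] is None:
        lines.append("  main component: no call (all candidates inconclusive)")
    else:
        margin = assignment["margin"]
        margin_txt = "n/a" if margin is None else f"{margin:.3f}"
        lines.append(
            f"  main component: {assignment['variety_id']}"
            f" [{assignment['status']}, margin {margin_txt}]"
        )
    for cand in doc["candidates"]:
        lines.append(
            f"  {cand['variety_id']:<16s} score={cand['inclusion_score']:.3f}"
            f" dist={cand['distance']:.3f} loci={cand['n_cotyped']}"
            f" -> {cand['presence_call']}"
        )
    if "panel_cumulative_pi" in doc:
        lines.append(f"  panel cumulative PI: {doc['panel_cumulative_pi']:.3e}")
    return "\n".join(lines)
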