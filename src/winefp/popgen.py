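"""Discrimination-power statistics for an SSR marker panel.

The probability of identity (PI) at one locus is the probability that two
individuals drawn at random from a Hardy-Weinberg population share a
genotype::

    PI = sum_i p_i^4  +  sum_{i<j} (2 p_i p_j)^2

which equals sum_g P(g)^2 over unordered genotypes g. Assuming independence
across loci, the cumulative PI of a panel is the product of per-locus
values; the smaller it is, the better the panel resolves varieties.

The random match probability (RMP) of a specific diploid profile is the
product over its typed loci of p_i^2 (homozygote) or 2 p_i p_j
(heterozygote).

Frequencies are estimated by plain allele counting from the diploid
reference genotypes; wines are DNA mixtures, not diploid draws, and are
excluded from frequency estimation unless explicitly requested through
pseudo-genotype sensitivity analysis at the call site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

from .errors import DomainError, UsageError
from .model import Locus, VarietyGenotype

import logging

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusFrequencies:
    """Relative allele frequencies at one locus (all positive, summing to 1)."""

    locus_name: str
    freqs: Mapping[int, float]
    n_genotypes: int = 0  # diploid individuals behind the estimate

    def __post_init__(self) -> None:
        freqs = {int(a): float(f) for a, f in self.freqs.items()}
        if not freqs:
            raise UsageError(f"{self.locus_name}: empty frequency table")
        if any(f <= 0 for f in freqs.values()):
            raise UsageError(f"{self.locus_name}: frequencies must be positive")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise UsageError(f"{self.locus_name}: frequencies must sum to 1")
        object.__setattr__(self, "freqs", freqs)


def estimate_frequencies(
    genotypes: Sequence[VarietyGenotype], locus: Locus | str
) -> LocusFrequencies:
    """Allele frequencies by gene counting: p_i = count_i / (2 * n typed)."""
    locus_name = locus.name if isinstance(locus, Locus) else locus
    counts: Dict[int, int] = {}
    n_typed = 0
    for g in genotypes:
        if locus_name not in g.calls:
            continue
        n_typed += 1
        for allele in g.calls[locus_name]:  # homozygotes contribute 2
            counts[allele] = counts.get(allele, 0) + 1
    if n_typed == 0:
        raise DomainError(f"no genotype typed at locus {locus_name}")
    total = 2 * n_typed
    return LocusFrequencies(
        locus_name, {a: c / total for a, c in counts.items()}, n_genotypes=n_typed
    )


def locus_pi(freqs: LocusFrequencies) -> float:
    """Plain probability of identity at one locus (HWE)."""
    p = list(freqs.freqs.values())
    total = sum(x**4 for x in p)
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            total += (2 * p[i] * p[j]) ** 2
    return total


def locus_pi_unbiased(freqs: LocusFrequencies, n_genotypes: int | None = None) -> float:
    """Small-sample unbiased PI estimator.

    Uses the standard moment correction in terms of the sample frequency
    power sums a_k = sum_i p_i^k with n the number of sampled gene copies
    (twice the diploid sample size); the plain estimator is biased upward
    for small cohorts.
    """
    n_ind = n_genotypes if n_genotypes is not None else freqs.n_genotypes
    if n_ind < 2:
        raise DomainError("unbiased PI needs at least 2 diploid genotypes")
    n = 2 * n_ind  # gene copies
    p = list(freqs.freqs.values())
    a2 = sum(x**2 for x in p)
    a3 = sum(x**3 for x in p)
    a4 = sum(x**4 for x in p)
    num = n**3 * (2 * a2**2 - a4) - 2 * n**2 * (a3 + 2 * a2) + n * (9 * a2 + 2) - 6
    den = (n - 1) * (n - 2) * (n - 3)
    return num / den


def cumulative_pi(pis: Sequence[float]) -> float:
    """Panel-wide PI: product of per-locus values (independent loci)."""
    if not list(pis):
        raise UsageError("cumulative_pi needs at least one locus PI")
    if any(not (0 < x <= 1) for x in pis):
        raise DomainError("per-locus PI values must lie in (0, 1]")
    result = 1.0
    for x in pis:
        result *= x
    return result


def panel_pi(
    genotypes: Sequence[VarietyGenotype],
    loci: Sequence[Locus | str],
    unbiased: bool = False,
) -> Dict[str, float]:
    """Per-locus PI table plus the cumulative product under key ``__cumulative__``."""
    table: Dict[str, float] = {}
    for locus in loci:
        freqs = estimate_frequencies(genotypes, locus)
        table[freqs.locus_name] = (
            locus_pi_unbiased(freqs) if unbiased else locus_pi(freqs)
        )
    table["__cumulative__"] = cumulative_pi(list(table.values()))
    return table


def random_match_probability(
    genotype: VarietyGenotype, freqs: Sequence[LocusFrequencies]
) -> float:
    """RMP of a diploid profile under the given frequency spectra.

    Loci untyped in the genotype or absent from the spectra are skipped
    (logged). An allele unseen in the spectrum substitutes the smallest
    observed frequency at that locus, again logged, so a single private
    allele does not zero out the product.
    """
    by_locus = {f.locus_name: f for f in freqs}
    product = 1.0
    n_used = 0
    for locus_name, (a, b) in sorted(genotype.calls.items()):
        table = by_locus.get(locus_name)
        if table is None:
            log.info("RMP: locus %s absent from frequency tables, skipped", locus_name)
            continue
        floor = min(table.freqs.values())
        pa = table.freqs.get(a)
        pb = table.freqs.get(b)
        if pa is None:
            log.warning("RMP: allele %d unseen at %s; using floor %.4g", a, locus_name, floor)
            pa = floor
        if pb is None:
            log.warning("RMP: allele %d unseen at %s; using floor %.4g", b, locus_name, floor)
            pb = floor
        product *= pa * pb if a == b else 2 * pa * pb
        n_used += 1
    if n_used == 0:
        raise DomainError(
            f"{genotype.variety_id}: no typed locus overlaps the frequency tables"
        )
    return product
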