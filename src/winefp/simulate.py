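"""Synthetic SSR genotyping data with wine-style degradation structure.

The generator stands in for the wet lab: it draws per-locus allele-frequency
spectra, samples diploid reference varieties under Hardy-Weinberg
equilibrium, and produces replicated wine peak observations in which

* every allele of every blend component is detected independently with a
  probability that *falls* with wine age and with *decreasing* blend
  proportion (allele drop-out),
* spurious alleles occasionally appear (allele drop-in), never coinciding
  with a true contributing allele at that locus,
* observed sizes are jittered around the integer allele so the binning and
  calibration stages have real work to do.

Detection probability follows::

    p_detect = p_base * proportion**gamma * exp(-lam * age_years)

clamped to [0, 1]. The defaults make a ~1.2% minor component's per-allele
detection probability about 0.48 at one year of age, so a three-replica
majority consensus retains some but not all of its alleles — an old minor
component fades from the fingerprint gradually rather than all at once.

All randomness flows from a single :class:`numpy.random.Generator`. The
number of random draws consumed per replica is independent of the outcomes
(unused jitters and heights are drawn and discarded), so two simulations
with the same seed but different ages are coupled draw-for-draw; detection
indicators are then monotone in age by construction, which makes ageing
experiments noise-free comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .errors import DomainError, UsageError
from .model import (
    Panel,
    Peak,
    ReplicaObservation,
    VarietyGenotype,
    WineProfile,
)


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Population allele frequencies at one locus, on the repeat-unit grid."""

    locus_name: str
    alleles: tuple
    freqs: tuple

    def __post_init__(self) -> None:
        alleles = tuple(int(a) for a in self.alleles)
        freqs = tuple(float(f) for f in self.freqs)
        if len(alleles) != len(freqs) or not alleles:
            raise UsageError(f"{self.locus_name}: alleles and freqs must align, non-empty")
        if any(f < 0 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-12:
            raise UsageError(f"{self.locus_name}: frequencies must be >= 0 and sum to 1")
        if any(b <= a for a, b in zip(alleles, alleles[1:])):
            raise UsageError(f"{self.locus_name}: alleles must be strictly increasing")
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "freqs", freqs)


@dataclass(frozen=True)
class BlendSpec:
    """Composition of one (possibly blended) wine to simulate."""

    wine_id: str
    components: Mapping[str, float]  # variety_id -> proportion in (0, 1]
    age_years: float = 0.0
    n_replicas: int = 3

    def __post_init__(self) -> None:
        if not self.components:
            raise UsageError(f"{self.wine_id}: blend needs at least one component")
        total = sum(self.components.values())
        if abs(total - 1.0) > 1e-9:
            raise UsageError(f"{self.wine_id}: proportions sum to {total}, expected 1")
        if any(p <= 0 for p in self.components.values()):
            raise UsageError(f"{self.wine_id}: proportions must be positive")
        if self.age_years < 0:
            raise UsageError(f"{self.wine_id}: age_years must be non-negative")
        if self.n_replicas < 3:
            raise UsageError(f"{self.wine_id}: wines need at least 3 technical replicas")
        object.__setattr__(self, "components", dict(self.components))


@dataclass(frozen=True)
class DropoutModel:
    """Parameters of the detection-probability law (see module docstring)."""

    p_base: float = 0.98
    gamma: float = 0.15
    lam: float = 0.05
    p_dropin: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.p_base <= 1):
            raise UsageError(f"p_base must be in (0,1], got {self.p_base}")
        if self.gamma < 0 or self.lam < 0:
            raise UsageError("gamma and lam must be non-negative")
        if not (0 <= self.p_dropin < 0.5):
            raise UsageError(f"p_dropin must be in [0,0.5), got {self.p_dropin}")


NOISE_FREE = DropoutModel(p_base=1.0, gamma=0.0, lam=0.0, p_dropin=0.0)

#: Size jitter half-width in bp; small enough that binning at repeat unit 2
#: is unambiguous.
JITTER_BP = 0.4


def detection_probability(model: DropoutModel, proportion: float, age_years: float) -> float:
    """Per-allele detection probability for a component of given proportion/age."""
    if proportion <= 0 or proportion > 1:
        raise DomainError(f"proportion must be in (0,1], got {proportion}")
    if age_years < 0:
        raise DomainError(f"age_years must be >= 0, got {age_years}")
    p = model.p_base * proportion**model.gamma * math.exp(-model.lam * age_years)
    return min(max(p, 0.0), 1.0)


def simulate_frequency_panel(
    panel: Panel,
    n_alleles_per_locus: int = 8,
    concentration: float = 1.0,
    seed: int = 0,
) -> List[AlleleFrequencySpectrum]:
    """Draw per-locus allele spectra: sizes on the repeat grid, Dirichlet freqs."""
    if n_alleles_per_locus < 1:
        raise UsageError("n_alleles_per_locus must be >= 1")
    if concentration <= 0:
        raise DomainError(f"concentration must be positive, got {concentration}")
    rng = np.random.default_rng(seed)
    spectra = []
    for locus in panel:
        span = locus.repeat_unit * (n_alleles_per_locus - 1)
        max_base = locus.size_max - span
        if max_base < locus.size_min:
            raise UsageError(
                f"{locus.name}: {n_alleles_per_locus} alleles do not fit in bounds"
            )
        n_starts = (max_base - locus.size_min) // locus.repeat_unit + 1
        base = locus.size_min + locus.repeat_unit * int(rng.integers(0, n_starts))
        alleles = tuple(base + locus.repeat_unit * k for k in range(n_alleles_per_locus))
        if n_alleles_per_locus == 1:
            freqs = (1.0,)
        else:
            f = rng.dirichlet([concentration] * n_alleles_per_locus)
            # Guard against exact zeros from extreme concentrations.
            f = np.clip(f, 1e-9, None)
            f = f / f.sum()
            freqs = tuple(float(x) for x in f)
        spectra.append(AlleleFrequencySpectrum(locus.name, alleles, freqs))
    return spectra


def simulate_variety(
    spectra: Sequence[AlleleFrequencySpectrum], variety_id: str, seed: int = 0
) -> VarietyGenotype:
    """Sample one diploid genotype: two independent draws per locus (HWE)."""
    if not spectra:
        raise UsageError("simulate_variety needs at least one spectrum")
    rng = np.random.default_rng(seed)
    calls = {}
    for spec in spectra:
        pair = rng.choice(spec.alleles, size=2, replace=True, p=spec.freqs)
        calls[spec.locus_name] = (int(pair[0]), int(pair[1]))
    return VarietyGenotype(variety_id, calls)


def true_profile(
    blend: BlendSpec, varieties: Mapping[str, VarietyGenotype], panel: Panel
) -> WineProfile:
    """Ground-truth wine profile: the union of component alleles per locus."""
    calls: Dict[str, set] = {}
    for vid in blend.components:
        genotype = varieties[vid]
        for locus, pair in genotype.calls.items():
            calls.setdefault(locus, set()).update(pair)
    return WineProfile(blend.wine_id, {k: frozenset(v) for k, v in calls.items()})


def simulate_wine_replicas(
    blend: BlendSpec,
    varieties: Mapping[str, VarietyGenotype] | Sequence[VarietyGenotype],
    model: DropoutModel,
    spectra: Sequence[AlleleFrequencySpectrum],
    seed: int = 0,
) -> List[ReplicaObservation]:
    """Simulate the replicated peak evidence for one blended wine.

    Per replica and locus, each distinct allele of each component is observed
    with :func:`detection_probability`; with probability ``p_dropin`` one
    spurious allele (never a true one) is added from the locus spectrum.
    Peak heights scale with the contributing proportion and carry lognormal
    noise; they are cosmetic and unused downstream.
    """
    if not isinstance(varieties, Mapping):
        varieties = {v.variety_id: v for v in varieties}
    missing = [vid for vid in blend.components if vid not in varieties]
    if missing:
        raise UsageError(f"{blend.wine_id}: no genotype for component(s) {missing}")
    spec_by_locus = {s.locus_name: s for s in spectra}
    rng = np.random.default_rng(seed)

    # Pre-resolve, per locus: (variety, proportion, distinct alleles) and the
    # drop-in candidate pool (spectrum alleles minus true alleles).
    loci = sorted({loc for vid in blend.components for loc in varieties[vid].calls})
    per_locus = []
    for locus in loci:
        contribs = []
        truth: set = set()
        for vid, prop in sorted(blend.components.items()):
            genotype = varieties[vid]
            if locus not in genotype.calls:
                continue
            alleles = sorted(set(genotype.calls[locus]))
            contribs.append((vid, prop, alleles))
            truth.update(alleles)
        spec = spec_by_locus.get(locus)
        if spec is not None:
            pool = [a for a in spec.alleles if a not in truth]
            pool_freqs = np.array([f for a, f in zip(spec.alleles, spec.freqs) if a not in truth])
            if pool_freqs.sum() > 0:
                pool_freqs = pool_freqs / pool_freqs.sum()
            else:
                pool = []
        else:
            pool, pool_freqs = [], np.array([])
        per_locus.append((locus, contribs, pool, pool_freqs))

    observations = []
    for rep in range(1, blend.n_replicas + 1):
        peaks: Dict[str, List[Peak]] = {}
        for locus, contribs, pool, pool_freqs in per_locus:
            locus_peaks: List[Peak] = []
            for vid, prop, alleles in contribs:
                p_det = detection_probability(model, prop, blend.age_years)
                for allele in alleles:
                    # Draw everything unconditionally to keep the stream
                    # length outcome-independent (see module docstring).
                    u = rng.uniform()
                    jitter = rng.uniform(-JITTER_BP, JITTER_BP)
                    height = prop * 1000.0 * rng.lognormal(0.0, 0.3)
                    if u < p_det:
                        locus_peaks.append(Peak(size=allele + jitter, height=height))
            # Drop-in: at most one spurious allele per locus and replica.
            u_dropin = rng.uniform()
            jitter = rng.uniform(-JITTER_BP, JITTER_BP)
            height = 0.05 * 1000.0 * rng.lognormal(0.0, 0.3)
            if len(pool) > 0:
                dropin_allele = int(rng.choice(pool, p=pool_freqs))
            else:
                rng.uniform()  # burn a draw so the stream length is fixed
                dropin_allele = None
            if dropin_allele is not None and u_dropin < model.p_dropin:
                locus_peaks.append(Peak(size=dropin_allele + jitter, height=height))
            if locus_peaks:
                peaks[locus] = locus_peaks
        observations.append(
            ReplicaObservation(
                sample_id=blend.wine_id, replicate_index=rep, peaks=peaks
            )
        )
    return observations


def simulate_reference_observations(
    genotype: VarietyGenotype,
    panel: Panel,
    n_replicas: int = 2,
    offset_by_locus: Mapping[str, float] | None = None,
    seed: int = 0,
) -> List[ReplicaObservation]:
    """Clean duplicate observations of a plant reference (internal calibrator).

    Plant DNA is abundant, so every allele is observed in every replica; an
    optional per-locus additive *offset* emulates systematic electrophoretic
    mobility shift, which the calibration stage should estimate back.
    """
    if n_replicas < 2:
        raise UsageError("plant references are run at least in double")
    offset_by_locus = dict(offset_by_locus or {})
    rng = np.random.default_rng(seed)
    observations = []
    for rep in range(1, n_replicas + 1):
        peaks: Dict[str, List[Peak]] = {}
        for locus, pair in sorted(genotype.calls.items()):
            shift = offset_by_locus.get(locus, 0.0)
            locus_peaks = []
            for allele in sorted(set(pair)):
                jitter = rng.uniform(-0.15, 0.15)
                height = 2000.0 * rng.lognormal(0.0, 0.2)
                locus_peaks.append(Peak(size=allele + shift + jitter, height=height))
            peaks[locus] = locus_peaks
        observations.append(
            ReplicaObservation(
                sample_id=genotype.variety_id, replicate_index=rep, peaks=peaks
            )
        )
    return observations
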