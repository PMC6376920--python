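"""From raw replicated peaks to validated profiles.

Three steps mirror how fragment-analysis data are read in practice:

1. **Calibration** — plant references of known genotype run in the same
   experiment anchor the size axis; per locus, the median difference between
   true and observed size is taken as an additive offset (the median is
   robust to a single aberrant calibrator peak).
2. **Binning** — corrected fractional sizes are rounded to the nearest
   integer on the locus grid; peaks falling outside the plausibility
   window are discarded (and logged upstream).
3. **Replica consensus** — an allele enters the validated profile only if
   its binned value recurs in at least ``min_count`` distinct technical
   replicas. The default is a majority rule, ceil(n/2), i.e. 2 of 3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set

from .errors import BinError, UsageError
from .model import Locus, Panel, ReplicaObservation, VarietyGenotype, WineProfile

log = logging.getLogger(__name__)


@dataclass
class CalibrationOffsets:
    """Per-locus additive size corrections estimated from plant calibrators."""

    offsets: Dict[str, float] = field(default_factory=dict)
    unreliable: Set[str] = field(default_factory=set)  # |offset| >= repeat_unit/2
    uncalibrated: Set[str] = field(default_factory=set)  # no matched calibrator peaks

    def offset(self, locus: str) -> float:
        return self.offsets.get(locus, 0.0)

    @classmethod
    def identity(cls) -> "CalibrationOffsets":
        return cls()


def estimate_offsets(
    reference_obs: Sequence[ReplicaObservation],
    reference_truth: Sequence[VarietyGenotype],
    panel: Panel,
) -> CalibrationOffsets:
    """Estimate per-locus offsets from plant references of known genotype.

    Each observed calibrator peak is matched to the nearest true allele of
    its sample within one repeat unit; unmatched peaks (calibrator
    artifacts) are ignored. offset = median(true - observed) per locus.
    """
    if not reference_obs:
        raise UsageError("offset estimation needs at least one reference observation")
    truth = {g.variety_id: g for g in reference_truth}
    residuals: Dict[str, List[float]] = {}
    for obs in reference_obs:
        genotype = truth.get(obs.sample_id)
        if genotype is None:
            raise UsageError(f"no reference genotype for sample {obs.sample_id}")
        for locus_name, peaks in obs.peaks.items():
            if locus_name not in panel or locus_name not in genotype.calls:
                continue
            repeat_unit = panel.locus(locus_name).repeat_unit
            true_alleles = sorted(set(genotype.calls[locus_name]))
            for peak in peaks:
                nearest = min(true_alleles, key=lambda a: abs(a - peak.size))
                if abs(nearest - peak.size) <= repeat_unit:
                    residuals.setdefault(locus_name, []).append(nearest - peak.size)

    result = CalibrationOffsets()
    for locus in panel:
        res = residuals.get(locus.name)
        if not res:
            result.offsets[locus.name] = 0.0
            result.uncalibrated.add(locus.name)
            continue
        res = sorted(res)
        mid = len(res) // 2
        median = res[mid] if len(res) % 2 else 0.5 * (res[mid - 1] + res[mid])
        result.offsets[locus.name] = median
        if abs(median) >= locus.repeat_unit / 2:
            result.unreliable.add(locus.name)
            log.warning(
                "calibration offset for %s is %.2f bp (>= half repeat unit): unreliable",
                locus.name,
                median,
            )
    return result


def bin_allele(raw_size: float, locus: Locus, offsets: CalibrationOffsets) -> int:
    """Round a calibrated size to the nearest integer on the locus grid.

    Rounding is half away from zero (150.5 -> 151), matching how allele
    sizes are conventionally read off electropherograms.
    """
    corrected = raw_size + offsets.offset(locus.name)
    if not locus.in_bounds(corrected):
        raise BinError(
            f"{locus.name}: corrected size {corrected:.2f} outside "
            f"[{locus.size_min}, {locus.size_max}]"
        )
    return int(math.floor(corrected + 0.5))


def consensus_profile(
    replicas: Sequence[ReplicaObservation],
    offsets: CalibrationOffsets,
    panel: Panel,
    min_count: int | None = None,
) -> WineProfile:
    """Validate alleles by recurrence across technical replicas.

    An allele enters the profile iff its binned value occurs in at least
    ``min_count`` distinct replicas (default: majority, ceil(n/2)). Loci
    where no allele reaches the threshold stay untyped. Provenance records,
    per typed locus, the number of replicas containing any retained peak.
    """
    if not replicas:
        raise UsageError("consensus needs at least one replica")
    sample_ids = {r.sample_id for r in replicas}
    if len(sample_ids) != 1:
        raise UsageError(f"replicas span multiple samples: {sorted(sample_ids)}")
    n = len(replicas)
    if n < 2:
        raise UsageError("consensus needs at least 2 replicas")
    if n == 2:
        log.warning("%s: only 2 replicas (plant double); wines should have >= 3",
                    replicas[0].sample_id)
    if min_count is None:
        min_count = math.ceil(n / 2)
    if min_count < 1 or min_count > n:
        raise UsageError(f"min_count {min_count} incompatible with {n} replicas")

    # allele -> set of replica indices in which it was seen (after binning)
    support: Dict[str, Dict[int, Set[int]]] = {}
    n_discarded = 0
    for replica in replicas:
        for locus_name, peaks in replica.peaks.items():
            if locus_name not in panel:
                continue
            locus = panel.locus(locus_name)
            for peak in peaks:
                if peak.out_of_bounds:
                    n_discarded += 1
                    continue
                try:
                    allele = bin_allele(peak.size, locus, offsets)
                except BinError:
                    n_discarded += 1
                    continue
                support.setdefault(locus_name, {}).setdefault(allele, set()).add(
                    replica.replicate_index
                )
    if n_discarded:
        log.info("%s: discarded %d out-of-bounds peak(s)", replicas[0].sample_id, n_discarded)

    calls: Dict[str, frozenset] = {}
    provenance: Dict[str, int] = {}
    for locus_name, allele_support in support.items():
        kept = {a for a, reps in allele_support.items() if len(reps) >= min_count}
        if kept:
            calls[locus_name] = frozenset(kept)
            replicas_with_signal = set()
            for a in kept:
                replicas_with_signal |= allele_support[a]
            provenance[locus_name] = len(replicas_with_signal)
    return WineProfile(sample_ids.pop(), calls, provenance=provenance)
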