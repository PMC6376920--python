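"""Domain types for SSR-based wine DNA fingerprinting.

A fingerprinting experiment compares two kinds of genetic profiles over a
shared panel of microsatellite (SSR) loci:

* grapevine *reference varieties* — diploid plants, so at most two allele
  sizes per locus;
* *wines* — DNA admixtures, so a locus may legitimately carry more than two
  validated allele sizes when the wine is a blend of several varieties.

Allele identity is the amplified fragment length in base pairs. Validated
profiles carry integer sizes on the binning grid; only raw electropherogram
peaks (:class:`ReplicaObservation`) hold fractional sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, NamedTuple, Sequence, Tuple

from .errors import UsageError

#: Default cap on validated alleles per wine locus: 2 copies for each of up
#: to 8 plausible blend components.
MAX_WINE_ALLELES = 16


@dataclass(frozen=True)
class Locus:
    """One SSR marker with its repeat unit and size plausibility window."""

    name: str
    repeat_unit: int = 2
    size_min: int = 80
    size_max: int = 400

    def __post_init__(self) -> None:
        if not self.name:
            raise UsageError("locus name must be non-empty")
        if self.repeat_unit < 1:
            raise UsageError(f"{self.name}: repeat_unit must be >= 1")
        if self.size_min >= self.size_max:
            raise UsageError(f"{self.name}: size_min must be < size_max")

    def in_bounds(self, size: float) -> bool:
        return self.size_min <= size <= self.size_max


class Panel:
    """Ordered collection of loci; typically 7-10 markers for grapevine work."""

    def __init__(self, loci: Sequence[Locus]):
        if not loci:
            raise UsageError("panel must contain at least one locus")
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise UsageError("duplicate locus names in panel")
        self._loci: Tuple[Locus, ...] = tuple(loci)
        self._by_name: Dict[str, Locus] = {l.name: l for l in loci}

    @property
    def loci(self) -> Tuple[Locus, ...]:
        return self._loci

    @property
    def names(self) -> List[str]:
        return [l.name for l in self._loci]

    def locus(self, name: str) -> Locus:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[Locus]:
        return iter(self._loci)

    def __len__(self) -> int:
        return len(self._loci)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Panel) and self._loci == other._loci

    def __repr__(self) -> str:
        return f"Panel({list(self.names)!r})"


# The nine markers used throughout for grapevine varietal identification,
# with generous plausibility windows around their published size ranges.
_DEFAULT_MARKERS = [
    ("VVS2", 110, 180),
    ("VVMD21", 230, 300),
    ("VVMD25", 230, 300),
    ("VVMD27", 160, 230),
    ("VVMD32", 230, 300),
    ("VVMD34", 230, 300),
    ("VrZag21", 180, 250),
    ("VrZag79", 230, 300),
    ("VrZag83", 170, 240),
]


def default_panel() -> Panel:
    """The standard 9-marker SSR panel for grapevine/wine genotyping."""
    return Panel([Locus(name, 2, lo, hi) for name, lo, hi in _DEFAULT_MARKERS])


@dataclass(frozen=True)
class VarietyGenotype:
    """A named diploid grapevine reference: locus -> unordered allele pair.

    Homozygotes are stored as a pair of equal sizes. Loci absent from
    ``calls`` are untyped. Pairs are normalised to ascending order so that
    equality is representation-independent.
    """

    variety_id: str
    calls: Mapping[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        norm = {}
        for locus, pair in self.calls.items():
            if len(pair) != 2:
                raise UsageError(
                    f"{self.variety_id}/{locus}: genotype call needs exactly 2 alleles"
                )
            a, b = int(pair[0]), int(pair[1])
            norm[locus] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "calls", norm)

    def allele_set(self, locus: str) -> frozenset:
        """Distinct alleles at *locus* (size 1 for homozygotes)."""
        return frozenset(self.calls[locus])

    @property
    def typed_loci(self) -> List[str]:
        return sorted(self.calls)


@dataclass(frozen=True)
class WineProfile:
    """A named wine: locus -> validated set of allele sizes.

    Blends may carry more than two alleles per locus; ``provenance`` records
    how many technical replicas supported each typed locus.
    """

    wine_id: str
    calls: Mapping[str, frozenset]
    provenance: Mapping[str, int] = field(default_factory=dict)
    max_alleles: int = MAX_WINE_ALLELES

    def __post_init__(self) -> None:
        norm = {}
        for locus, alleles in self.calls.items():
            aset = frozenset(int(a) for a in alleles)
            if not aset:
                raise UsageError(f"{self.wine_id}/{locus}: empty allele set for typed locus")
            if len(aset) > self.max_alleles:
                raise UsageError(
                    f"{self.wine_id}/{locus}: {len(aset)} alleles exceeds cap {self.max_alleles}"
                )
            norm[locus] = aset
        object.__setattr__(self, "calls", norm)
        object.__setattr__(self, "provenance", dict(self.provenance))

    def allele_set(self, locus: str) -> frozenset:
        return self.calls[locus]

    @property
    def typed_loci(self) -> List[str]:
        return sorted(self.calls)

    def __eq__(self, other: object) -> bool:
        # Provenance is bookkeeping metadata, not part of the profile identity.
        if not isinstance(other, WineProfile):
            return NotImplemented
        return self.wine_id == other.wine_id and self.calls == other.calls

    def __hash__(self) -> int:
        return hash((self.wine_id, tuple(sorted(self.calls))))


class Peak(NamedTuple):
    """One electropherogram peak: fractional size (bp) and fluorescence height."""

    size: float
    height: float
    out_of_bounds: bool = False


@dataclass(frozen=True)
class ReplicaObservation:
    """Raw peaks of one technical replica (one PCR) of one sample."""

    sample_id: str
    replicate_index: int
    peaks: Mapping[str, Tuple[Peak, ...]]

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise UsageError(
                f"{self.sample_id}: replicate_index must be >= 1, got {self.replicate_index}"
            )
        object.__setattr__(
            self, "peaks", {loc: tuple(pks) for loc, pks in self.peaks.items()}
        )


@dataclass
class Dataset:
    """A panel plus the reference varieties and wines typed against it."""

    panel: Panel
    varieties: List[VarietyGenotype] = field(default_factory=list)
    wines: List[WineProfile] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [v.variety_id for v in self.varieties] + [w.wine_id for w in self.wines]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise UsageError(f"duplicate sample ids: {sorted(dupes)}")
        for v in self.varieties:
            for locus in v.calls:
                if locus not in self.panel:
                    raise UsageError(f"{v.variety_id}: call references unknown locus {locus}")
        for w in self.wines:
            for locus in w.calls:
                if locus not in self.panel:
                    raise UsageError(f"{w.wine_id}: call references unknown locus {locus}")

    @property
    def sample_ids(self) -> List[str]:
        return [v.variety_id for v in self.varieties] + [w.wine_id for w in self.wines]

    def variety(self, variety_id: str) -> VarietyGenotype:
        for v in self.varieties:
            if v.variety_id == variety_id:
                return v
        raise KeyError(variety_id)

    def wine(self, wine_id: str) -> WineProfile:
        for w in self.wines:
            if w.wine_id == wine_id:
                return w
        raise KeyError(wine_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.panel == other.panel
            and sorted(self.varieties, key=lambda v: v.variety_id)
            == sorted(other.varieties, key=lambda v: v.variety_id)
            and sorted(self.wines, key=lambda w: w.wine_id)
            == sorted(other.wines, key=lambda w: w.wine_id)
        )
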