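"""Readers and writers for the tabular formats the pipeline touches.

Three plain-text formats are supported:

* **genotype CSV** — validated calls, one row per (sample, locus) with
  columns ``sample_id,sample_type,locus,alleles``; alleles are
  ``/``-separated integer sizes. ``sample_type`` is ``grapevine`` (diploid,
  exactly two alleles) or ``wine`` (any non-empty allele set; repeated rows
  for the same wine/locus union their alleles). A blank alleles field marks
  the locus untyped and the row is ignored.
* **peak TSV** — raw capillary-electrophoresis fragment export, columns
  ``sample_id,replicate,marker,size,height`` with fractional sizes.
* **dataset JSON** — a single document bundling panel and calls, used by
  the report writer.

Distance matrices additionally serialise to square PHYLIP and CSV.
"""

from __future__ import annotations

import csv
import io as _io
import json
import math
from typing import Dict, List, Sequence, TextIO, Tuple, Union

import pandas as pd

from .errors import ConflictError, ParseError, UsageError
from .model import (
    Dataset,
    Locus,
    Panel,
    Peak,
    ReplicaObservation,
    VarietyGenotype,
    WineProfile,
)

Stream = Union[str, TextIO]

GENOTYPE_HEADER = ["sample_id", "sample_type", "locus", "alleles"]
PEAK_HEADER = ["sample_id", "replicate", "marker", "size", "height"]


def _as_text(stream: Stream) -> TextIO:
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


def read_genotype_table(stream: Stream, panel: Panel, label: str = "") -> Dataset:
    """Parse a genotype CSV into a :class:`Dataset`.

    Grapevine rows must carry exactly two alleles; duplicate
    (grapevine, locus) rows are a conflict. Wine rows with the same
    (wine, locus) key union their allele sets, mirroring how alleles
    accumulate over multiple experiments.
    """
    reader = csv.reader(_as_text(stream))
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty genotype stream (missing header)")
    if [h.strip() for h in header] != GENOTYPE_HEADER:
        raise ParseError(f"unexpected genotype header: {header}")

    vine_calls: Dict[str, Dict[str, Tuple[int, int]]] = {}
    wine_calls: Dict[str, Dict[str, set]] = {}
    order: List[Tuple[str, str]] = []  # (sample_type, sample_id) first-seen order

    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 4:
            raise ParseError(f"line {lineno}: expected 4 fields, got {len(row)}")
        sample_id, sample_type, locus, alleles_field = (c.strip() for c in row)
        if sample_type not in ("wine", "grapevine"):
            raise ParseError(f"line {lineno}: unknown sample_type {sample_type!r}")
        if locus not in panel:
            raise ParseError(f"line {lineno}: locus {locus!r} not in panel")
        if not alleles_field:
            # Blank allele field records an untyped locus.
            continue
        try:
            alleles = [int(a) for a in alleles_field.split("/")]
        except ValueError:
            raise ParseError(f"line {lineno}: malformed alleles field {alleles_field!r}")
        if sample_id not in vine_calls and sample_id not in wine_calls:
            order.append((sample_type, sample_id))
        if sample_type == "grapevine":
            if len(alleles) != 2:
                raise ParseError(
                    f"line {lineno}: grapevine {sample_id} at {locus} has "
                    f"{len(alleles)} alleles (need exactly 2)"
                )
            calls = vine_calls.setdefault(sample_id, {})
            if locus in calls:
                raise ConflictError(
                    f"line {lineno}: duplicate grapevine call for ({sample_id}, {locus})"
                )
            calls[locus] = (alleles[0], alleles[1])
        else:
            wine_calls.setdefault(sample_id, {}).setdefault(locus, set()).update(alleles)

    varieties = [
        VarietyGenotype(sid, vine_calls[sid])
        for (stype, sid) in order
        if stype == "grapevine"
    ]
    wines = [
        WineProfile(sid, {loc: frozenset(a) for loc, a in wine_calls[sid].items()})
        for (stype, sid) in order
        if stype == "wine"
    ]
    return Dataset(panel=panel, varieties=varieties, wines=wines, label=label)


def write_genotype_table(dataset: Dataset) -> str:
    """Serialise a Dataset to genotype CSV (loci in panel order)."""
    out = _io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(GENOTYPE_HEADER)
    for v in dataset.varieties:
        for locus in dataset.panel.names:
            if locus in v.calls:
                a, b = v.calls[locus]
                writer.writerow([v.variety_id, "grapevine", locus, f"{a}/{b}"])
    for w in dataset.wines:
        for locus in dataset.panel.names:
            if locus in w.calls:
                alleles = "/".join(str(a) for a in sorted(w.calls[locus]))
                writer.writerow([w.wine_id, "wine", locus, alleles])
    return out.getvalue()


def read_peak_table(stream: Stream, panel: Panel) -> List[ReplicaObservation]:
    """Parse a peak TSV into per-(sample, replicate) observations.

    Sizes outside the locus plausibility window are retained but flagged
    ``out_of_bounds`` so the consensus stage can discard and log them.
    """
    df = pd.read_csv(_as_text(stream), sep="\t", dtype=str)
    if list(df.columns) != PEAK_HEADER:
        raise ParseError(f"unexpected peak header: {list(df.columns)}")
    grouped: Dict[Tuple[str, int], Dict[str, List[Peak]]] = {}
    order: List[Tuple[str, int]] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        sample_id = str(row.sample_id).strip()
        marker = str(row.marker).strip()
        try:
            replicate = int(str(row.replicate))
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer replicate {row.replicate!r}")
        try:
            size = float(row.size)
            height = float(row.height)
        except ValueError:
            raise ParseError(f"line {lineno}: malformed size/height")
        if size < 0:
            raise ParseError(f"line {lineno}: negative size {size}")
        if height <= 0:
            raise ParseError(f"line {lineno}: non-positive height {height}")
        if marker not in panel:
            raise ParseError(f"line {lineno}: marker {marker!r} not in panel")
        locus = panel.locus(marker)
        peak = Peak(size=size, height=height, out_of_bounds=not locus.in_bounds(size))
        key = (sample_id, replicate)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        grouped[key].setdefault(marker, []).append(peak)
    return [
        ReplicaObservation(
            sample_id=sid,
            replicate_index=rep,
            peaks={loc: tuple(pks) for loc, pks in grouped[(sid, rep)].items()},
        )
        for sid, rep in order
    ]


def write_peak_table(observations: Sequence[ReplicaObservation]) -> str:
    """Serialise replica observations to peak TSV (simulator output format)."""
    out = _io.StringIO()
    out.write("\t".join(PEAK_HEADER) + "\n")
    for obs in observations:
        for marker in sorted(obs.peaks):
            for peak in obs.peaks[marker]:
                out.write(
                    f"{obs.sample_id}\t{obs.replicate_index}\t{marker}"
                    f"\t{peak.size:.2f}\t{peak.height:.1f}\n"
                )
    return out.getvalue()


def merge_datasets(datasets: Sequence[Dataset], policy: str = "union") -> Dataset:
    """Merge several datasets into one, as when building a profiling databank.

    Samples are concatenated; duplicate sample ids must agree call-for-call
    (restricted to the merged panel) or a :class:`ConflictError` is raised.
    The merged panel is the union or intersection of the input panels,
    according to *policy*.
    """
    if not datasets:
        raise UsageError("merge_datasets needs at least one dataset")
    if policy not in ("union", "intersection"):
        raise UsageError(f"unknown merge policy {policy!r}")

    loci: Dict[str, Locus] = {}
    common = set(datasets[0].panel.names)
    for ds in datasets:
        for locus in ds.panel:
            if locus.name in loci and loci[locus.name] != locus:
                raise ConflictError(f"locus {locus.name} defined inconsistently")
            loci.setdefault(locus.name, locus)
        common &= set(ds.panel.names)
    if policy == "union":
        keep = list(loci)
    else:
        keep = [n for n in loci if n in common]
    if not keep:
        raise UsageError("merged panel is empty under intersection policy")
    # Preserve first-dataset ordering, then first-appearance for new loci.
    ordered = [n for ds in datasets for n in ds.panel.names]
    seen: List[str] = []
    for n in ordered:
        if n in keep and n not in seen:
            seen.append(n)
    panel = Panel([loci[n] for n in seen])

    varieties: Dict[str, VarietyGenotype] = {}
    wines: Dict[str, WineProfile] = {}
    order: List[Tuple[str, str]] = []
    for ds in datasets:
        for v in ds.varieties:
            calls = {loc: pair for loc, pair in v.calls.items() if loc in panel}
            cand = VarietyGenotype(v.variety_id, calls)
            if v.variety_id in varieties:
                if varieties[v.variety_id] != cand:
                    bad = _differing_loci(varieties[v.variety_id].calls, cand.calls)
                    raise ConflictError(
                        f"conflicting duplicate grapevine {v.variety_id} at loci {bad}"
                    )
            else:
                varieties[v.variety_id] = cand
                order.append(("grapevine", v.variety_id))
        for w in ds.wines:
            calls = {loc: a for loc, a in w.calls.items() if loc in panel}
            cand = WineProfile(w.wine_id, calls)
            if w.wine_id in wines:
                if wines[w.wine_id] != cand:
                    bad = _differing_loci(wines[w.wine_id].calls, cand.calls)
                    raise ConflictError(
                        f"conflicting duplicate wine {w.wine_id} at loci {bad}"
                    )
            else:
                wines[w.wine_id] = cand
                order.append(("wine", w.wine_id))

    label = "+".join(ds.label for ds in datasets if ds.label)
    return Dataset(
        panel=panel,
        varieties=[varieties[sid] for t, sid in order if t == "grapevine"],
        wines=[wines[sid] for t, sid in order if t == "wine"],
        label=label,
    )


def _differing_loci(a: dict, b: dict) -> List[str]:
    keys = set(a) | set(b)
    return sorted(k for k in keys if a.get(k) != b.get(k))


# ---------------------------------------------------------------------------
# JSON bundle
# ---------------------------------------------------------------------------

def dataset_to_json(dataset: Dataset) -> str:
    doc = {
        "label": dataset.label,
        "panel": [
            {
                "name": l.name,
                "repeat_unit": l.repeat_unit,
                "size_min": l.size_min,
                "size_max": l.size_max,
            }
            for l in dataset.panel
        ],
        "varieties": [
            {"variety_id": v.variety_id, "calls": {k: list(p) for k, p in sorted(v.calls.items())}}
            for v in dataset.varieties
        ],
        "wines": [
            {
                "wine_id": w.wine_id,
                "calls": {k: sorted(a) for k, a in sorted(w.calls.items())},
                "provenance": dict(sorted(w.provenance.items())),
            }
            for w in dataset.wines
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def dataset_from_json(text: str) -> Dataset:
    doc = json.loads(text)
    panel = Panel(
        [
            Locus(p["name"], p["repeat_unit"], p["size_min"], p["size_max"])
            for p in doc["panel"]
        ]
    )
    varieties = [
        VarietyGenotype(v["variety_id"], {k: tuple(p) for k, p in v["calls"].items()})
        for v in doc["varieties"]
    ]
    wines = [
        WineProfile(
            w["wine_id"],
            {k: frozenset(a) for k, a in w["calls"].items()},
            provenance=w.get("provenance", {}),
        )
        for w in doc["wines"]
    ]
    return Dataset(panel=panel, varieties=varieties, wines=wines, label=doc.get("label", ""))


# ---------------------------------------------------------------------------
# Distance matrix writers
# ---------------------------------------------------------------------------

def distance_to_phylip(labels: Sequence[str], values) -> str:
    """Square PHYLIP format: count line, then one row per labelled sample."""
    lines = [f"{len(labels)}"]
    for i, lab in enumerate(labels):
        row = " ".join(f"{values[i][j]:.6f}" for j in range(len(labels)))
        lines.append(f"{lab:<12s}{row}")
    return "\n".join(lines) + "\n"


def distance_to_csv(labels: Sequence[str], values) -> str:
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    return df.to_csv(float_format="%.6f")


def is_nan(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)
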