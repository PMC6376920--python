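"""End-to-end orchestration: raw input to admixture report bundle.

``run_wdf`` executes the whole fingerprinting analysis: (optional) replica
consensus from a peak table, allele-sharing distances, Neighbor-Joining
with bootstrap support, per-wine candidate assessment, PCA ordination, and
panel PI — writing every intermediate as a re-loadable plain-text artifact.
Outputs are a pure function of config + seed: no wall-clock, no
filesystem-order dependence.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import io as wio
from .admixture import (
    DEFAULT_EPSILON,
    DEFAULT_THETA,
    admixture_report,
    assess_candidates,
    assign_main_variety,
    ordinate,
    report_to_json,
)
from .clustering import (
    DEFAULT_N_BOOT,
    DEFAULT_SCALES,
    multiscale_bootstrap,
    neighbor_joining,
)
from .consensus import CalibrationOffsets, consensus_profile, estimate_offsets
from .distance import DEFAULT_MIN_COTYPED, distance_matrix
from .errors import UsageError, WinefpError
from .model import Dataset, Panel, WineProfile, default_panel
from .popgen import panel_pi

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; defaults mirror the module-level defaults."""

    genotype_csv: Optional[str] = None
    peak_tsv: Optional[str] = None
    reference_csv: Optional[str] = None  # calibrator genotypes for peak input
    outdir: str = "wdf_out"
    min_count: Optional[int] = None  # consensus; None = majority rule
    min_cotyped: int = DEFAULT_MIN_COTYPED
    metric: str = "dice"
    method: str = "nj"
    scales: Tuple[float, ...] = DEFAULT_SCALES
    n_boot: int = DEFAULT_N_BOOT
    theta: float = DEFAULT_THETA
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0
    run_bootstrap: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in doc:
            doc["scales"] = tuple(float(x) for x in doc["scales"])
        return cls(**doc)

    def validate(self) -> None:
        if self.seed < 0:
            raise UsageError("seed must be a non-negative integer")
        if self.genotype_csv is None and self.peak_tsv is None:
            raise UsageError("either genotype_csv or peak_tsv input is required")
        for label, path in (
            ("genotype_csv", self.genotype_csv),
            ("peak_tsv", self.peak_tsv),
            ("reference_csv", self.reference_csv),
        ):
            if path is not None and not Path(path).exists():
                raise UsageError(f"{label} does not exist: {path}")
        if self.peak_tsv is not None and self.reference_csv is None:
            raise UsageError("peak input needs reference_csv with calibrator genotypes")


def run_wdf(config: RunConfig, panel: Optional[Panel] = None) -> Dict:
    """Execute the full pipeline; returns the report bundle (also written to disk).

    On any stage failure the partially written output directory is removed
    and the error re-raised with the stage name.
    """
    config.validate()
    panel = panel or default_panel()
    outdir = Path(config.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = "input"
        if config.peak_tsv is not None:
            with open(config.reference_csv) as fh:
                refs = wio.read_genotype_table(fh, panel)
            observations = wio.read_peak_table(
                Path(config.peak_tsv).read_text(), panel
            )
            stage = "consensus"
            # Calibrate against any observation whose sample is a known reference.
            ref_ids = {v.variety_id for v in refs.varieties}
            ref_obs = [o for o in observations if o.sample_id in ref_ids]
            offsets = (
                estimate_offsets(ref_obs, refs.varieties, panel)
                if ref_obs
                else CalibrationOffsets.identity()
            )
            wine_obs: Dict[str, List] = {}
            for obs in observations:
                if obs.sample_id not in ref_ids:
                    wine_obs.setdefault(obs.sample_id, []).append(obs)
            wines = [
                consensus_profile(reps, offsets, panel, config.min_count)
                for _, reps in sorted(wine_obs.items())
            ]
            dataset = Dataset(panel=panel, varieties=refs.varieties, wines=wines)
        else:
            with open(config.genotype_csv) as fh:
                dataset = wio.read_genotype_table(fh, panel)
        if not dataset.wines or not dataset.varieties:
            raise UsageError("run needs at least one wine and one reference variety")
        (outdir / "genotypes.csv").write_text(wio.write_genotype_table(dataset))

        # ------------------------------------------------------------------
        stage = "distance"
        profiles = list(dataset.varieties) + list(dataset.wines)
        dm = distance_matrix(profiles, config.min_cotyped, config.metric)
        (outdir / "distance.phy").write_text(
            wio.distance_to_phylip(dm.labels, dm.values)
        )
        (outdir / "distance.csv").write_text(wio.distance_to_csv(dm.labels, dm.values))

        # ------------------------------------------------------------------
        stage = "tree"
        tree = neighbor_joining(dm) if len(dm.labels) >= 3 else None
        newick = tree.to_newick() if tree else None
        if newick:
            (outdir / "tree.nwk").write_text(newick + "\n")

        stage = "support"
        supports = []
        if config.run_bootstrap and len(dm.labels) >= 4 and len(panel) >= 2:
            supports = multiscale_bootstrap(
                dataset,
                method=config.method,
                scales=config.scales,
                n_boot=config.n_boot,
                min_cotyped=config.min_cotyped,
                seed=config.seed,
                metric=config.metric,
            )
            _write_support_csv(outdir / "support.csv", supports)

        # ------------------------------------------------------------------
        stage = "popgen"
        pi_table = panel_pi(dataset.varieties, list(panel))
        cumulative = pi_table["__cumulative__"]

        stage = "ordination"
        ordination = ordinate(profiles) if len(profiles) >= 2 else None

        stage = "admixture"
        reports = {}
        assessment_rows = []
        for wine in dataset.wines:
            assessments = assess_candidates(
                wine, dataset.varieties, config.theta, config.min_cotyped
            )
            assignment = assign_main_variety(assessments, config.epsilon)
            reports[wine.wine_id] = admixture_report(
                wine,
                assessments,
                assignment,
                newick=newick,
                supports=supports or None,
                ordination=ordination,
                cumulative_pi=cumulative,
            )
            assessment_rows.extend(assessments)
        _write_assessment_csv(outdir / "assessments.csv", assessment_rows)

        stage = "report"
        bundle = {
            "pi_per_locus": {k: v for k, v in sorted(pi_table.items()) if k != "__cumulative__"},
            "cumulative_pi": cumulative,
            "wines": {wid: reports[wid] for wid in sorted(reports)},
            "seed": config.seed,
        }
        (outdir / "report.json").write_text(report_to_json(bundle))
        return bundle
    except Exception as exc:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        if isinstance(exc, WinefpError):
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        raise


def _write_support_csv(path: Path, supports: Sequence) -> None:
    lines = ["cluster,bp,au,v,c,n_boot"]
    for s in supports:
        cluster = "|".join(sorted(s.cluster))
        lines.append(f"{cluster},{s.bp:.4f},{s.au:.4f},{s.v:.4f},{s.c:.4f},{s.n_boot}")
    path.write_text("\n".join(lines) + "\n")


def _write_assessment_csv(path: Path, rows: Sequence) -> None:
    lines = ["wine_id,variety_id,inclusion_score,distance,n_cotyped,presence_call"]
    for a in rows:
        lines.append(
            f"{a.wine_id},{a.variety_id},{a.inclusion_score:.6f},"
            f"{a.distance:.6f},{a.n_cotyped},{a.presence_call}"
        )
    path.write_text("\n".join(lines) + "\n")
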