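"""Simulation studies exercising the whole pipeline against known truth.

These routines generate synthetic panels, varieties and wines, push them
through calibration, consensus and candidate assessment, and score the
results against the generator's ground truth. They are the package's
parameter-recovery harness: the studies they implement are

* **monovarietal recovery** — a 100% single-variety wine of age <= 3 years
  must be assigned its true variety among several candidates;
* **blend compatibility** — in an 85/15 two-variety blend at age 0 both
  components should be called compatible at the default threshold
  (85% mirrors the usual varietal-labelling minimum);
* **minor-component ageing** — a ~1.2% trace component's compatibility
  rate must decay with wine age; simulations at different ages share the
  same random draws (common random numbers), so the decay is monotone by
  construction and the study measures the rate, not sampling noise.

Every study takes an integer seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .admixture import (
    DEFAULT_EPSILON,
    DEFAULT_THETA,
    assess_candidates,
    assign_main_variety,
)
from .consensus import consensus_profile, estimate_offsets
from .distance import DEFAULT_MIN_COTYPED
from .model import Panel, VarietyGenotype, default_panel
from .simulate import (
    BlendSpec,
    DropoutModel,
    simulate_frequency_panel,
    simulate_reference_observations,
    simulate_variety,
    simulate_wine_replicas,
)

_SEED_MOD = 2**31 - 1


def _spawn_seeds(seed: int, n: int, salt: int) -> List[int]:
    rng = np.random.default_rng((seed + 1000003 * salt) % _SEED_MOD)
    return [int(s) for s in rng.integers(0, _SEED_MOD, size=n)]


@dataclass
class ScenarioResult:
    assigned: bool
    calls: Dict[str, str]  # variety_id -> presence_call
    main_variety: str | None


def _run_scenario(
    components: Dict[int, float],
    age_years: float,
    seed: int,
    n_candidates: int = 4,
    panel: Panel | None = None,
    model: DropoutModel | None = None,
    theta: float = DEFAULT_THETA,
) -> ScenarioResult:
    """One synthetic wine through simulate -> calibrate -> consensus -> assess."""
    panel = panel or default_panel()
    model = model or DropoutModel()
    spectra = simulate_frequency_panel(panel, n_alleles_per_locus=8, seed=seed)
    varieties = [
        simulate_variety(spectra, f"V{k}", seed=(seed + 7919 * (k + 1)) % _SEED_MOD)
        for k in range(n_candidates)
    ]
    blend = BlendSpec(
        wine_id="W",
        components={f"V{k}": p for k, p in components.items()},
        age_years=age_years,
        n_replicas=3,
    )
    replicas = simulate_wine_replicas(
        blend, varieties, model, spectra, seed=(seed + 104729) % _SEED_MOD
    )
    # Plant references in double, as internal calibrators.
    ref_obs = []
    for k, v in enumerate(varieties):
        ref_obs.extend(
            simulate_reference_observations(
                v, panel, n_replicas=2, seed=(seed + 15485863 * (k + 1)) % _SEED_MOD
            )
        )
    offsets = estimate_offsets(ref_obs, varieties, panel)
    wine = consensus_profile(replicas, offsets, panel)
    assessments = assess_candidates(wine, varieties, theta=theta)
    assignment = assign_main_variety(assessments, DEFAULT_EPSILON)
    return ScenarioResult(
        assigned=assignment.status == "assigned",
        calls={a.variety_id: a.presence_call for a in assessments},
        main_variety=assignment.variety_id,
    )


def monovarietal_recovery(
    n_runs: int = 100, max_age: float = 3.0, seed: int = 0
) -> int:
    """Number of runs (of *n_runs*) where a 100% V0 wine is assigned V0."""
    seeds = _spawn_seeds(seed, n_runs, salt=1)
    ages = np.random.default_rng((seed + 17) % _SEED_MOD).uniform(0, max_age, n_runs)
    successes = 0
    for run_seed, age in zip(seeds, ages):
        result = _run_scenario({0: 1.0}, float(age), run_seed)
        if result.assigned and result.main_variety == "V0":
            successes += 1
    return successes


def blend_compatibility(
    n_runs: int = 100,
    proportions: Sequence[float] = (0.85, 0.15),
    age_years: float = 0.0,
    theta: float = DEFAULT_THETA,
    seed: int = 0,
) -> int:
    """Runs where *every* blend component is called compatible."""
    seeds = _spawn_seeds(seed, n_runs, salt=2)
    components = {k: p for k, p in enumerate(proportions)}
    successes = 0
    for run_seed in seeds:
        result = _run_scenario(components, age_years, run_seed, theta=theta)
        if all(result.calls[f"V{k}"] == "compatible" for k in components):
            successes += 1
    return successes


def minor_component_age_curve(
    ages: Sequence[float] = (0.0, 1.0, 3.0, 5.0, 7.0),
    minor_proportion: float = 0.012,
    n_runs: int = 100,
    seed: int = 0,
) -> Dict[float, float]:
    """Compatibility rate of a trace component at each age.

    The same per-run seeds are reused at every age: because the simulator
    consumes a fixed number of random draws regardless of outcomes, runs at
    different ages are coupled draw-for-draw and each run's compatibility
    indicator is non-increasing in age.
    """
    seeds = _spawn_seeds(seed, n_runs, salt=3)
    components = {0: 1.0 - minor_proportion, 1: minor_proportion}
    rates: Dict[float, float] = {}
    for age in ages:
        hits = 0
        for run_seed in seeds:
            result = _run_scenario(components, float(age), run_seed)
            if result.calls["V1"] == "compatible":
                hits += 1
        rates[float(age)] = hits / n_runs
    return rates


def dropin_survival_rate(n_runs: int = 1000, seed: int = 0) -> float:
    """Mean number of drop-in alleles surviving consensus, per 9-locus profile."""
    from .simulate import true_profile

    panel = default_panel()
    model = DropoutModel()
    seeds = _spawn_seeds(seed, n_runs, salt=4)
    survivors = 0
    for run_seed in seeds:
        spectra = simulate_frequency_panel(panel, n_alleles_per_locus=8, seed=run_seed)
        variety = simulate_variety(spectra, "V0", seed=(run_seed + 7919) % _SEED_MOD)
        blend = BlendSpec(wine_id="W", components={"V0": 1.0}, n_replicas=3)
        replicas = simulate_wine_replicas(
            blend, [variety], model, spectra, seed=(run_seed + 104729) % _SEED_MOD
        )
        from .consensus import CalibrationOffsets

        wine = consensus_profile(replicas, CalibrationOffsets.identity(), panel)
        truth = true_profile(blend, {"V0": variety}, panel)
        for locus, alleles in wine.calls.items():
            survivors += len(alleles - truth.calls.get(locus, frozenset()))
    return survivors / n_runs
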