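"""Simulate replicated wine genotyping evidence and validate it by consensus.

Builds a 9-locus SSR panel, samples four reference varieties under
Hardy-Weinberg equilibrium, simulates three technical replicas of an 85/15
two-variety blend (with allele drop-out/drop-in and size jitter), then
calibrates, bins, and validates the alleles across replicas.
"""

from winefp import (
    BlendSpec,
    DropoutModel,
    consensus_profile,
    default_panel,
    estimate_offsets,
    simulate_frequency_panel,
    simulate_reference_observations,
    simulate_variety,
    simulate_wine_replicas,
    true_profile,
)

panel = default_panel()
spectra = simulate_frequency_panel(panel, n_alleles_per_locus=8, seed=1)
varieties = [simulate_variety(spectra, f"V{k}", seed=10 + k) for k in range(4)]

blend = BlendSpec("demo_wine", {"V0": 0.85, "V1": 0.15}, age_years=1.0, n_replicas=3)
replicas = simulate_wine_replicas(blend, varieties, DropoutModel(), spectra, seed=2)

# Plant references run in double act as internal size calibrators.
ref_obs = []
for k, v in enumerate(varieties):
    ref_obs.extend(simulate_reference_observations(v, panel, seed=20 + k))
offsets = estimate_offsets(ref_obs, varieties, panel)

wine = consensus_profile(replicas, offsets, panel)
truth = true_profile(blend, {v.variety_id: v for v in varieties}, panel)

print(f"wine {wine.wine_id}: {len(wine.calls)} of {len(panel)} loci typed")
for locus in panel.names:
    got = sorted(wine.calls.get(locus, ()))
    want = sorted(truth.calls.get(locus, ()))
    missing = set(want) - set(got)
    print(f"  {locus:8s} validated={got}  truth={want}"
          + (f"  dropped={sorted(missing)}" if missing else ""))

# Validated alleles are those recurring in >= 2 of 3 replicas; alleles of the
# 15% component may drop, and rare drop-ins are filtered by the recurrence rule.
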