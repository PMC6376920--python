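"""Probability of identity: how well does the panel resolve varieties?

Estimates allele frequencies by gene counting over a cohort of simulated
reference genotypes, then reports per-locus and cumulative PI. The
cumulative PI is the probability that two random varieties share a full
multi-locus genotype: the smaller, the more discriminating the panel.
"""

from winefp import (
    default_panel,
    estimate_frequencies,
    locus_pi,
    cumulative_pi,
    random_match_probability,
    simulate_frequency_panel,
    simulate_variety,
)

panel = default_panel()
spectra = simulate_frequency_panel(panel, n_alleles_per_locus=8, seed=7)
cohort = [simulate_variety(spectra, f"V{k}", seed=100 + k) for k in range(50)]

pis = []
freq_tables = []
print(f"{'locus':10s} {'alleles':>7s} {'PI':>10s}")
for locus in panel:
    freqs = estimate_frequencies(cohort, locus)
    freq_tables.append(freqs)
    pi = locus_pi(freqs)
    pis.append(pi)
    print(f"{locus.name:10s} {len(freqs.freqs):7d} {pi:10.4f}")

print(f"\ncumulative PI over {len(panel)} loci: {cumulative_pi(pis):.3e}")
print("(= probability two random varieties share the full profile)")

rmp = random_match_probability(cohort[0], freq_tables)
print(f"random match probability of {cohort[0].variety_id}: {rmp:.3e}")
# Each extra locus multiplies PI down by ~0.1-0.3; a 9-locus panel reaches
# the 1e-9..1e-11 range, ample for distinguishing grapevine varieties.
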