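# winefp — wine DNA fingerprinting and admixture analysis

Residual *Vitis vinifera* DNA survives in wine and can be genotyped at
microsatellite (SSR) loci, yielding a *wine DNA fingerprint*: per locus, a
set of validated allele sizes that is the union of the contributing
grapevine varieties' alleles, eroded by allele drop-out and contaminated
by occasional drop-ins. `winefp` is a library for analysts who want to
turn such replicated, noisy genotyping evidence into defensible varietal
conclusions — and for method developers who need a fully synthetic test
bed for that inference.

It covers, end to end:

- **Replica consensus** — calibrate fragment sizes against plant
  references run as internal calibrators, bin to the allele grid, and keep
  alleles recurring in ≥ ceil(n/2) of n technical replicas.
- **Panel statistics** — per-locus and cumulative probability of identity
  `PI = Σᵢ pᵢ⁴ + Σ_{i<j} (2pᵢpⱼ)²` (product over loci), and random match
  probability of a profile.
- **Distances and trees** — per-locus Dice similarity on allele sets
  averaged into an allele-sharing distance (with a comparability threshold
  on co-typed loci), Saitou–Nei Neighbor-Joining and UPGMA, Newick export.
- **Cluster confidence** — multiscale bootstrap over panel loci with the
  BP curve fitted as z_r = v√r + c/√r, giving the approximately unbiased
  p-value AU = 1 − Φ(v − c) per cluster.
- **Admixture calls** — an inclusion score (fraction of a candidate's
  allele copies found in the wine) with threshold θ, presence/absence
  calls per candidate, and main-variety assignment with an ambiguity
  margin.
- **Synthetic data** — Hardy–Weinberg varieties from Dirichlet spectra and
  blended wines with age- and proportion-dependent dropout
  `p_detect = p_base · proportion^γ · e^(−λ·age)`, so every stage is
  testable without a wet lab.
- **Multilayer integration** — supra-adjacency matrices over data layers,
  walk counts, communicability exp(M), layer aggregation and interlayer-
  strength fitting.

## Worked example

Score four candidate varieties against a simulated young 85% Merlot / 15%
Zinfandel blend (three technical replicas, consensus-validated):

```bash
python examples/03_wine_admixture_calls.py
```

```
Wine red_947
  main component: Merlot [assigned, margin 0.059]
  Merlot           score=1.000 dist=0.233 loci=9 -> compatible
  Zinfandel        score=0.944 dist=0.293 loci=9 -> compatible
  PinotNoir        score=0.722 dist=0.444 loci=9 -> excluded
  CabernetS        score=0.556 dist=0.563 loci=9 -> excluded
```

Reading: every Merlot allele copy appears in the wine (score 1.000) and
Merlot is the closest profile, so it is assigned as the main component
with a 0.059 distance margin over the runner-up. Zinfandel — the declared
15% minor component — retains 94% of its allele copies and is called
compatible at θ = 0.75. The two varieties that are not in the blend sit
at clearly larger distances and are excluded.

The other example scripts demonstrate consensus validation
(`01_simulate_and_consensus.py`), panel PI and RMP
(`02_panel_discrimination_pi.py`, cumulative PI ≈ 7.7 × 10⁻¹¹ for the
9-locus default panel over 50 simulated varieties), NJ trees with BP/AU
support (`04_tree_and_bootstrap.py`), and multiplex-network aggregation
(`05_multilayer_integration.py`).

A thin CLI mirrors the library for shell use:

```bash
winefp simulate --blend "V0=0.85,V1=0.15" --seed 1 \
    --out-peaks peaks.tsv --out-references refs.csv --out-truth truth.json
winefp run --peaks peaks.tsv --references refs.csv --outdir out --seed 1
```

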