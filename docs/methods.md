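# Methods

`winefp` implements the dry-lab side of SSR-based wine varietal
authentication: from replicated microsatellite peak observations of wines
and grapevine references to validated profiles, panel discrimination
statistics, distance trees with bootstrap support, candidate-variety
presence calls, and a multiplex-network data-integration model. This note
records the models, parameter choices and numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Data model

A **panel** is an ordered list of SSR loci, each with a repeat unit
(default 2 bp) and a size plausibility window. The default panel carries
the nine markers standard in grapevine work (VVS2, VVMD21/25/27/32/34,
VrZag21/79/83). Alleles are integer fragment sizes in bp; fractional sizes
exist only in raw peak observations. A **reference variety** is diploid:
at most two alleles per locus. A **wine** is a DNA admixture: a locus may
carry any number of validated alleles (capped at 16 = 2 copies x 8
plausible blend components), because a blend unions the alleles of its
component varieties.

## Replica consensus and calibration

Electrophoretic mobility drifts between experiments, so sizes are
calibrated against plant references of known genotype run in the same
experiment: per locus, each calibrator peak is matched to its nearest true
allele within one repeat unit and the **median** of (true − observed)
residuals is the additive offset. The median resists a single aberrant
calibrator peak; offsets at or above half a repeat unit are flagged
unreliable, and loci with no matched peaks are flagged uncalibrated with
offset 0. Offsets are per locus, not global, because mobility varies with
fragment size.

Corrected sizes are binned by rounding half away from zero to the integer
grid; peaks outside the plausibility window are discarded and logged.
An allele enters the validated profile only if its binned value recurs in
at least `min_count` distinct technical replicas; the default is the
majority rule ceil(n/2), i.e. 2 of 3 — the standard forensic consensus for
low-template DNA. Raising `min_count` can only remove alleles
(monotonicity), and with the generator defaults (1% drop-in per locus and
replica, 3 replicas) the expected number of spurious alleles surviving
consensus is far below 0.01 per 9-locus profile, because a drop-in must
recur at the same size in two independent replicas.

One deliberate reading: recurrence is counted **after** binning, so two
raw sizes that bin to the same integer support each other. Counting modal
raw sizes before binning would be an alternative; binning first is simpler
and robust to sub-bp jitter.

## Panel discrimination statistics

Allele frequencies are estimated by gene counting over the diploid
reference genotypes only — wines are mixtures, not diploid draws, and are
excluded from frequency estimation. Per locus, the probability of identity
under Hardy–Weinberg equilibrium is

    PI = Σ_i p_i⁴ + Σ_{i<j} (2 p_i p_j)²  =  Σ_g P(g)²,

and the panel's cumulative PI is the product over loci (independence
assumed). The plain estimator is the primary one; a small-sample unbiased
variant (moment correction in the frequency power sums a_k with n = number
of sampled gene copies) is provided and was verified by Monte Carlo
unbiasedness against enumerated population PI. The random match
probability of a diploid profile is the product over typed loci of p²
(homozygote) or 2pq (heterozygote); alleles unseen in the spectrum take
the smallest observed frequency (logged) so one private allele does not
zero the product.

## Distances

Profiles are compared on allele sets with the Dice coefficient per locus,
2|a∩b|/(|a|+|b|), averaged over loci typed in both; distance = 1 − mean
similarity. Dice handles multi-allelic wine sets and reduces to the
classical proportion-of-shared-alleles measure on heterozygous diploid
pairs; Jaccard is available behind a flag. Pairs with fewer than
`min_cotyped` shared typed loci (default 4 of 7–10) are flagged
incomparable and pinned to the maximal distance 1.0 rather than treated as
missing, so tree builders always receive a complete matrix; the
comparability mask is carried into reports.

## Trees and cluster confidence

Neighbor-Joining follows Saitou–Nei exactly: join the pair minimising
Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), standard two-point branch
lengths, negative lengths clamped to zero (logged), ties broken by the
lexicographically smallest label pair (internal nodes inherit the smallest
leaf label of their subtree) so output is deterministic. The unrooted
result is stored with a trifurcating root. On additive matrices NJ is
exact; the test suite verifies topology and all path lengths to 1e-9 on
random trees up to 12 leaves. UPGMA (arithmetic-average update, ultrametric
heights = distance/2) provides rooted dendrograms.

Cluster confidence uses multiscale bootstrap with **loci** as the
resampling unit — the natural exchangeable element of an SSR panel. At
each scale r in {0.5, 0.6, …, 1.4}, round(r·L) loci are drawn with
replacement (default 1000 replicates per scale), distances and the tree
are rebuilt, and each original cluster's recurrence frequency BP_r is
recorded; clusters are leaf bipartitions for NJ and subtree leaf sets for
dendrograms. The comparability threshold is scaled with r
(max(1, round(r·min_cotyped))), otherwise strongly downscaled resamples
would be uniformly incomparable. The AU p-value comes from the weighted
least-squares fit of z_r = Φ⁻¹(1 − BP_r) to v√r + c/√r with binomial
delta-method weights n·φ(z_r)²/(BP_r(1−BP_r)); AU = 1 − Φ(v − c). WLS
rather than maximum likelihood: at 1000 replicates per scale the
difference is negligible and the fit is a two-parameter linear solve.
Curves stuck at 0 (or 1) across all scales fall back to AU = 0 (or 1);
otherwise at least two scales with BP strictly inside (0,1) are required.
For bootstrap resampling the per-locus pair similarities are precomputed
once as (L × n × n) tensors, making each replicate a weighted average plus
one tree build.

## Candidate assessment

The **inclusion score** of a candidate variety against a wine is the
fraction of the candidate's allele copies (homozygotes weigh 2) present in
the wine's allele sets, over loci typed in both. It is a deterministic
score, not a calibrated probability — a calibrated posterior would require
a dropout likelihood model, which is out of scope. The compatibility
threshold θ = 0.75 tolerates roughly one dropped allele copy per two loci
at seven co-typed loci, matching degraded-DNA expectations. Foreign wine
alleles never lower a candidate's score (they affect only the distance) —
the score asks "is this variety in the blend?", not "is the blend only
this variety?". Candidates with fewer than `min_cotyped` shared loci are
inconclusive. The main varietal component is the comparable candidate with
the smallest distance; if the runner-up is within ε = 0.02 the assignment
is flagged ambiguous, the wanted behaviour for variety pairs nearly
indistinguishable on a small SSR panel.

PCA ordination encodes profiles as binary (locus, allele) incidence
vectors (presence/absence, since wines carry sets rather than genotype
counts), mean-centres columns and projects on the leading principal axes;
the degenerate all-identical case returns zero coordinates and zero
explained variance instead of 0/0.

## Synthetic-data generator

The generator is the wet lab's stand-in and defines the conditions under
which the pipeline is validated. Per locus it draws a spectrum of 8
alleles on the repeat grid (base position seeded per locus) with symmetric
Dirichlet(1) frequencies; varieties are two independent draws per locus
(HWE). A wine is a proportion-weighted blend with age; per replica and
locus, each allele of each component is detected with probability

    p_detect = p_base · proportion^γ · exp(−λ · age_years),

defaults p_base = 0.98, γ = 0.15, λ = 0.05. The functional form is a
modelling choice: only qualitative facts are available (a ~1.2% minor
component visible at one year of age but not at five; a varietal profile
degrading by year five), and the defaults place a 1.2% component's
per-allele detection near 0.48 at age 1 — so a 3-replica majority
consensus keeps some but not all of its alleles, and the component fades
progressively with age. Drop-ins occur with probability 0.01 per locus and
replica, drawn from the locus spectrum excluding true alleles (so a
drop-in can never masquerade as truth). Observed sizes are jittered
uniformly within ±0.4 bp, unambiguous at repeat unit 2; peak heights scale
with proportion and carry lognormal noise but are cosmetic — nothing
downstream consumes them. Plant-reference observations are clean
duplicates with optional systematic mobility shift for exercising
calibration.

All randomness flows from one seeded generator, and the number of draws
consumed per replica is independent of outcomes (unused jitters and
heights are drawn and discarded). Consequence: two simulations with the
same seed and different ages are coupled draw-for-draw, detection
indicators are monotone in age, and ageing comparisons are exact rather
than statistical — the age-decay study reports a monotone curve by
construction and measures its rate.

Not modelled: PCR stutter, heterozygote peak imbalance, microbial/yeast
background DNA, real electropherogram traces, and population structure
among varieties (spectra are independent across loci). Passing
parameter-recovery tests therefore demonstrates the pipeline's logic under
the stated degradation model, not performance on any particular real
cohort.

## Multilayer integration

The multiplex model couples h similarity layers over the same wines
through the supra-adjacency matrix M: layer adjacencies on the diagonal
blocks, ω_ij·I off-diagonal, with ω symmetric in [0,1]. Walk counts are
entries of M^k; communicability weights all walks by 1/k! and is the
matrix exponential exp(M) including the k = 0 identity term — the standard
definition. The aggregate wine-by-wine similarity averages exp(M) over all
h² layer-copy pairs (diagonal zeroed); the arithmetic mean is the simplest
defensible collapse, and the regression flavour of aggregation is exactly
the ω fit: a grid search (default a single shared scalar ω, step 0.1, ties
to the smallest ω) minimising the squared gap between aggregate and a
response network. The full ω-matrix search is available behind a flag for
up to 4 layers; its grid grows exponentially in the number of layer pairs.
No empirical wine dataset exists for this model, so its validation is
entirely property-based (block structure, walk-enumeration oracle,
truncated-series oracle, self-consistent ω recovery).

## Problem sizes and tolerances

The test suite and the acceptance script use: 100-run parameter-recovery
studies (monovarietal, 85/15 blend, and the 1.2%-trace age grid
{0,1,3,5,7} years at 100 runs per age); 200 random additive matrices with
4–12 leaves for NJ exactness at 1e-9; 100 random spectra (≤10 alleles) for
the PI enumeration oracle at 1e-12; exhaustive graphs n ≤ 5 for walk
counting and a 20-term series at 1e-9 for communicability; bootstrap runs
in tests at 30–200 replicates (the 1000-replicate default is exercised by
the model-fit oracle rather than brute force). These sizes keep the full
suite in seconds while leaving each check statistically meaningful.

## Known limitations

- Presence calls are thresholded scores, not likelihood ratios; no mixture
  proportion estimation.
- PI uses plain product-rule independence across loci; no θ-correction for
  population substructure.
- The distance threshold rule pins incomparable pairs at distance 1.0,
  which can compress deep branches when many loci are untyped.
- The dropout law is a parsimonious parametric choice calibrated to
  qualitative observations only.
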