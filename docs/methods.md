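# Methods

## Problem

Statistical phasing assigns each heterozygous allele of a diploid genotype
to one of the two parental haplotypes using haplotype sharing across a
cohort. At biobank scale the difficulty is concentrated at rare variants:
a variant seen in a handful of carriers offers almost no direct linkage
information, and a singleton (minor allele count, MAC = 1) offers none at
all. phasekit implements the three-model strategy suited to this regime:

1. **Common variants (MAF ≥ 0.1%)** are phased jointly into a *haplotype
   scaffold* by a Gibbs sampler with a diploid Li–Stephens copying model
   and PBWT-selected conditioning states.
2. **Rare heterozygotes (MAF < 0.1%, MAC ≥ 2)** are phased one at a time
   onto the fixed scaffold: a per-variant conditioning set is assembled
   from PBWT long matches plus a carrier-restricted pass, and a haploid
   Li–Stephens forward–backward imputes, for each target haplotype, the
   probability of carrying the minor allele.
3. **Singletons** are phased by a coalescent-inspired rule: the minor
   allele goes to the target haplotype whose longest shared segment through
   the site is *shorter* (an older local common ancestor leaves more time
   for a new mutation on that lineage).

A compound-heterozygosity screen, trio/duo switch-error evaluation,
imputation-concordance metrics (aggregate r², non-reference discordance),
site QC and VCF I/O complete the toolkit.

## Models

### Diploid Li–Stephens scaffold sampler

Each sample's haplotype pair is resampled conditional on the current
haplotypes of the others. States are ordered pairs (j, k) of conditioning
haplotypes; per-haplotype transitions between adjacent scaffold sites are
`(1 − ρ_m)·δ + ρ_m/K` with

    ρ_m = 1 − exp(−0.04 · n_eff · d_cm / K),

`d_cm` the genetic distance and `K` the number of conditioning states;
genotype emissions multiply per-haplotype copying errors (mismatch
probability `theta`), summing both orderings at heterozygous sites.
Haplotype pairs are drawn by forward-filtering backward-sampling (FFBS)
restricted to genotype-consistent pairs.

Two algorithmic details proved essential and are deliberate design
choices:

* **Round-robin local state selection.** Conditioning candidates are the
  nearest PBWT sorted-order neighbours of both target haplotypes at a grid
  of anchor sites (16 by default). The panel of `k_states` is filled
  round-robin across anchors rather than by global similarity ranking: a
  target haplotype is a mosaic, and each mosaic segment needs its own
  locally best copying source. Global ranking leaves segments without a
  source and the Gibbs chain plateaus at several percent switch error;
  round-robin selection reaches ~1% under the same budget.
* **Greedy polish sweeps.** Pure Gibbs sampling sustains a self-reinforcing
  error equilibrium: copying another sample's haplotype *exactly*,
  including its switch errors, costs nothing at genotype-emission level,
  so errors circulate, and each fresh draw re-injects sampling noise. The
  last half of the main iterations therefore decode the most probable pair
  path (greedy backward pass) instead of sampling, which settles the panel
  into a posterior mode. Burn-in and the first main iterations remain
  stochastic so the chain can escape the random initialisation.

Per-heterozygote orientation confidence for common variants is the
agreement frequency between the main-phase sampled orientations (aligned
to stable haplotype labels by majority vote against the pre-update pair)
and the final haplotypes, mapped to [0.5, 1].

### Rare-variant copying model

For a rare heterozygote of sample *i*, the conditioning set is the union
of (1) a general pass — nearest PBWT neighbours of both target haplotypes
at the two common sites flanking the variant, in both forward and backward
indexes — and (2) a carrier-restricted pass over the samples carrying the
minor allele, located through the sparse carrier index. Heterozygous
conditioning samples contribute the minor allele on *both* haplotypes
(forced homozygosity: their own phase at the site is unknown); all
non-carrier haplotypes contribute the major allele. The set is therefore
guaranteed polymorphic, which is what lets the copying model contrast the
two phases.

A haploid Li–Stephens forward–backward runs over the scaffold with the
conditioning haplotypes as a local reference panel; copying posteriors are
read at the two flanking common sites and averaged with equal weight
(edge variants use their single nearest anchor twice). Writing `p0`, `p1`
for the two haplotypes' minor-allele probabilities and conditioning on the
heterozygosity constraint (exactly one haplotype carries the minor allele):

    P(minor on hap0) = p0 (1 − p1) / (p0 (1 − p1) + p1 (1 − p0)).

The call's confidence is `max(P, 1 − P) ∈ [0.5, 1]`. Exact ties are
broken by a seeded coin and flagged. Singletons carry confidence exactly
0.5; their orientation comes from the shortest-match rule, with the
longest shared segment per haplotype found by an exact early-terminating
scan over all other haplotypes (the PBWT guarantees only per-side maxima,
not the maximal *through*-site match, so the scan is authoritative; it is
cheap because unrelated haplotypes diverge within a few sites).

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 1e-3 | common/rare boundary (boundary value is common) |
| `LSParams.n_eff` | 15 000 | effective population size scaling ρ; appropriate for human cohorts |
| `LSParams.theta` | 1e-4 | copying mismatch probability |
| `LSParams.k_states` | 16 | conditioning haplotypes per sample/query |
| `LSParams.n_burnin` / `n_main` | 5 / 10 | Gibbs sweeps; the last `n_main/2` are greedy polish |
| `k_each_side` | 4 | PBWT neighbours per side per direction in match queries |
| `max_states` (rare) | 16 | conditioning-set cap before deduplication |

`n_eff` must match the demography of the data. The simulation experiments
use `n_eff = 100`, `theta = 3e-4` (`workflows.SIM_LS_KW`): the synthetic
panels coalesce to a small founder pool within ~30 generations, i.e. an
effective population orders of magnitude smaller than a human cohort, and
with `n_eff = 15 000` the switch probability saturates near 1 between
adjacent simulated sites, destroying all linkage.

## Synthetic panels

`simdata.simulate_panel` is a forward-in-time mosaic simulation, not a
coalescent: `n_founders` founder haplotypes carry ancestral variation
(derived counts from a power-law SFS with exponent `sfs_exponent`); the
population of `2·n_samples` haplotypes is then copied forward through
`n_meioses` generations of random mating with Poisson crossovers (1 per
100 cM per meiosis); rare variation enters as point mutations placed on a
random haplotype of a random generation and inherited from there. Defaults:
5 cM region at 1 site/kb (the scale of one WGS phasing chunk), 30
generations, founder pool `max(40, n/10)`, 30% ancestral sites.

This reproduces the features the method exploits: identity-by-descent
sharing at all depths (recent pairs share whole-region segments, founder
level pairs share ~1 cM), rare carriers that co-descend from the mutation
lineage and hence share long matches, a rare-variant excess (most
mutations die or stay rare), and a natural singleton age signal —
mutations observed at MAC 1 preferentially sit on lineages with sparse
recent relatedness, so the carrier haplotype has a systematically shorter
longest-match (the shortest-match rule recovers ~60–75% of simulated
singletons from true haplotypes, against 50% for a random rule).

What the generator does **not** emulate: mutation/genotyping error inside
the copying process (genotype errors are injected post hoc and
independently), gene conversion, variable recombination maps (uniform cM/bp
unless a map is supplied), population structure and admixture, and the
sheer cohort sizes of a biobank. Passing tests therefore demonstrate the
correctness and qualitative behaviour of the algorithms (error rates well
below random, monotone gains with sample size, calibrated confidences) —
not the absolute error rates achievable on real data.

Trios are explicit meioses from sample parents, so offspring phase is
known exactly; parents are flagged for exclusion from phasing cohorts, as
when accuracy is measured on offspring against parental truth.
`singleton_fraction` forces exact-MAC-1 sites by down-sampling carriers to
one uniformly chosen carrier; such forced singletons carry no age signal
(their carrier is exchangeable) and are used for bookkeeping tests and the
random-orientation baseline, while accuracy experiments rely on the
natural singletons.

## Evaluation

Truth phase for an offspring heterozygote is deduced from parental
genotypes where transmission is unique (trio) or the single parent is
homozygous (duo); impossible transmissions are flagged and excluded. The
switch error rate is the fraction of successive deducible heterozygote
pairs whose relative orientation disagrees with the truth; each error is
attributed to the MAC bin of the *current* heterozygote (default bins
{1}, 2–5, 6–10, 11–20, 21–50, 51–100, 101–500, common). SER is invariant
to a global haplotype swap per sample; samples with fewer than two
deducible heterozygotes are skipped with a warning. Per-call correctness
in the simulation experiments aligns estimated to true haplotype labels
locally (majority vote over the nearest 25 common heterozygous sites), so
distal scaffold switches do not contaminate the score of a local call.

NRD and aggregate r² follow the standard imputation-concordance
definitions; bins with a constant pooled vector report a missing r², not
zero. Parent–offspring candidate pairs are filtered with strict
inequalities: kinship in (0.1767, 0.3553), IBS0 < 0.0012, age gap > 15
years, and different-sex parents for trios.

## Compound heterozygosity

A gene × individual is an event when at least one qualifying heterozygous
variant sits on each haplotype. Singletons never qualify; calls below a
confidence threshold can be dropped before assessment. Rare
homozygous-minor genotypes knock out both copies on their own; they are
counted in a separate column and never as compound-het events. The
expected number of compound-het individuals per gene under independent
phase is `Σ_i 1 − (1/2)^(v_i − 1)` over individuals with `v_i ≥ 2`
qualifying heterozygotes, and the randomized-phase control redraws every
orientation with a fair coin. Enrichment against gene lists uses the
two-sided Fisher exact test (hypergeometric tail summation via scipy) with
the sample cross-product odds ratio and Woolf log CI; a zero cell triggers
the Haldane–Anscombe 0.5 correction for the OR/CI only (flagged), never
for the p-value.

## Numerical and degenerate-input choices

* All HMM recursions rescale per site; probabilities are clamped to
  [1e-12, 1 − 1e-12] before forming phase odds.
* Genetic distances between adjacent scaffold sites are floored at 1e-7 cM
  so co-located sites do not produce ρ = 0 ties; without a genetic map,
  match lengths and distances fall back to site counts.
* Missing genotypes are imputed to the major allele before scaffold
  phasing, with a logged count.
* Monomorphic sites are classified `monomorphic` and bypass every phasing
  model (they are emitted as constant columns).
* PBWT divergence convention: `div[k][i]` is the first site of the match
  between sorted haplotypes `i` and `i−1`, with sentinel `k+1` at `i = 0`;
  neighbour ties break toward the lower haplotype ordinal.
* Ligation flips a chunk per sample when the majority of shared buffer
  heterozygotes disagree; samples without a shared buffer heterozygote
  keep an arbitrary relative orientation and are counted.
* Site QC order (first failing reason attributed): Hardy–Weinberg exact
  mid-p < 1e-30, missingness (missing GT or GQ = 0) > 10%, observed/expected
  heterozygote ratio outside [0.5, 1.5], AAscore < 0.5 (only when the INFO
  field exists), FILTER ≠ PASS (when required). "Heterozygote excess" is
  read as the observed/HWE-expected het-count ratio.

## Problem sizes in the shipped experiments

The accuracy experiments phase cohorts of n = 2000 samples × 5000 sites
(ten replicate seeds) and n = 500 × 5000 (five paired seeds); the
compound-het calibration uses 5000 individuals × 120 genes × 25 variants;
the random-singleton baseline pools ≥ 2000 offspring singletons from five
trio cohorts. These sizes give a few hundred rare heterozygotes and a few
hundred singletons per replicate, enough to separate the method cleanly
from the 50% baselines while keeping a full run of the suite on one CPU
in the tens of minutes.

## Known limitations

* The scaffold sampler is a plain diploid Li–Stephens Gibbs/greedy scheme;
  it does not reproduce segment-compression, IBD2 handling or
  multithreading of production phasing engines, and its absolute error
  rates on real biobank data would differ.
* Rare variants are phased at their two anchor sites only; they are never
  inserted into the scaffold HMM lattice, and the scaffold is never
  re-estimated from rare-variant information.
* Anchor posteriors are averaged with equal weights; distance-weighted
  averaging is a possible refinement.
* Chunked phasing + ligation is exposed but the default workflow phases a
  region in one chunk; results are not guaranteed bit-identical across
  different chunkings.
* The Woolf CI is a large-sample approximation; with very small gene
  counts its coverage is approximate even with the Haldane–Anscombe
  correction.
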