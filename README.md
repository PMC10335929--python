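# phasekit

Statistical haplotype phasing of rare variants in large sequenced cohorts,
with the evaluation metrics and downstream screens that go with it.

Sequencing cohorts are dominated by rare variation: most sites have a
minor allele carried by a handful of individuals, and a large fraction are
singletons (minor allele count, MAC = 1). Classical population phasing
works well for common variants but carries almost no information at these
sites. phasekit implements a three-model strategy for exactly this regime,
aimed at statistical geneticists who need phased rare variants — for
example, to call compound-heterozygous gene knockouts — and at method
developers who want a compact, fully tested reference implementation with
a built-in simulator.

## The models

1. **Common variants (MAF ≥ 0.1%)** are phased jointly into a haplotype
   *scaffold* by a Gibbs sampler under the diploid Li–Stephens model. Each
   sample is re-phased conditional on the others with a small panel of
   conditioning haplotypes chosen through a positional Burrows–Wheeler
   transform (PBWT): the nearest sorted-order neighbours of both target
   haplotypes at a grid of anchor sites. Switch probabilities follow
   ρ_m = 1 − exp(−0.04·N_e·d_cM/K); emissions allow a copying error θ.
2. **Rare heterozygotes (MAF < 0.1%, MAC ≥ 2)** are phased one at a time
   onto the scaffold. An individualized conditioning set combines PBWT long
   matches around the variant with a carrier-restricted search; heterozygous
   carriers contribute the minor allele on *both* haplotypes (forced
   homozygosity), guaranteeing a polymorphic panel. A haploid Li–Stephens
   forward–backward imputes each target haplotype's minor-allele
   probability p at the two flanking common sites, and the phase posterior
   is P(minor on hap0) = p0(1−p1) / (p0(1−p1) + p1(1−p0)), reported as a
   confidence PP ∈ [0.5, 1].
3. **Singletons** carry no cohort linkage information; they are phased by a
   coalescent argument: the minor allele is assigned to the target
   haplotype whose longest shared segment through the site is *shorter*
   (older local common ancestor ⇒ more time for a new mutation), with
   PP fixed at 0.5.

Alongside the phasing engine the package provides trio/duo truth
derivation and MAC-stratified switch error rates (SER), imputation
concordance (aggregate r², non-reference discordance), parent–offspring
selection filters, a compound-heterozygosity screen with expected-count
calibration and Fisher enrichment, VCF I/O with multiallelic decomposition
and site QC, and a genealogy-based cohort simulator
(`phasekit.simdata`) that makes the whole stack testable end to end.
See `docs/methods.md` for the models, assumptions and limitations.

## Worked example

Simulate a cohort of 500 samples over a 5 cM region (2,000 sites), phase
it, and score against the simulation truth:

```python
from phasekit.simdata import SimConfig, simulate_panel
from phasekit.scaffold import LSParams
from phasekit.workflows import phase_cohort
from phasekit.evaluation import switch_error_rate, truth_codes_from_haplotypes

cfg = SimConfig(n_founders=50, n_samples=500, n_sites=2000, seed=7)
truth, genotypes, records = simulate_panel(cfg)

params = LSParams(seed=7, n_eff=100, theta=3e-4)   # demography-matched
result = phase_cohort(genotypes, records, site_cm=truth.site_cm,
                      positions=truth.positions_bp, params=params, seed=7)

codes = truth_codes_from_haplotypes(truth.true_haplotypes, genotypes)
report = switch_error_rate(result.phased, codes, records)
print(report.table.to_string(index=False))
print(f"overall SER: {report.overall:.4%}")
```

Output:

```
    bin  n_pairs  n_errors     rate
      1       96        40 0.416667
    2-5      349        29 0.083095
   6-10      367        12 0.032698
  11-20     1064        24 0.022556
  21-50     3211        34 0.010589
 51-100     6538        62 0.009483
101-500    49644       356 0.007171
   501+        0         0      NaN
overall SER: 0.9091%
rare-variant calls: 97 (97 singletons, confidence 0.5 each)
```

Reading it: each row is a minor-allele-count bin; `rate` is the fraction
of successive heterozygote pairs whose relative phase disagrees with the
truth, attributed to the bin of the current heterozygote. Common variants
phase at ~0.7–1% SER, error rises as MAC falls, and singletons — where
naive methods sit at 50% — come out at ~42% from the shortest-match rule.
At this cohort size (1,000 haplotypes) every site with MAC ≥ 2 is above
the 0.1% frequency threshold, so the 97 rare-model calls are all
singletons; larger cohorts (see the experiments) also exercise the
rare-heterozygote copying model, which reaches ~1% error at MAC 2–20 with
high-confidence calls (PP ≥ 0.99) roughly halving that again.

A command-line interface mirrors the workflow on VCF files:

```bash
phasekit phase-common --input raw.vcf --output scaffold.vcf --seed 1
phasekit phase-rare   --input raw.vcf --output phased.vcf  --seed 1
phasekit evaluate --estimated phased.vcf --truth truth.vcf --out ser.tsv
phasekit comphet --phased phased.vcf --annotations ann.tsv --out events.tsv
```

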