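"""Synthetic biobank-like haplotype panels for end-to-end testing.

The generator is a forward-in-time mosaic simulation rather than a full
coalescent: a small pool of founder haplotypes (carrying the common,
SFS-distributed ancestral variation) is copied forward through
``n_meioses`` generations of random mating with Poisson crossovers (1 per
100 cM per meiosis), and rare variation enters as point mutations placed on
random haplotypes of random intermediate generations and inherited from
there.  This cheap construction produces the three properties the phasing
models exploit:

* **LD / IBD-like sharing at all scales** — pairs of sample haplotypes
  coalesce at varying depths (recent siblings share whole-region segments,
  founder-level relatives share short ones).
* **Rare-allele sharing through recent co-ancestry** — carriers of a
  surviving mutation descend from its carrier lineage, so they share long
  haplotype matches around the site.
* **A singleton age signal** — mutations observed at MAC 1 sit
  preferentially on lineages with sparse recent relatedness, so the carrier
  haplotype has systematically shorter longest-matches than its partner,
  which is exactly what the shortest-match singleton model assumes.

Trios/duos are produced by explicit meioses from sample parents, giving
exact inheritance truth for switch-error evaluation.  ``singleton_fraction``
additionally forces sites to exact MAC 1 by down-sampling carriers (useful
for format and bookkeeping tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .variants import DEFAULT_MAF_THRESHOLD, records_from_matrix

BP_PER_SITE = 1000  # physical spacing scale of simulated sites


@dataclass
class SimConfig:
    """Study conditions for one simulated panel.

    Defaults describe a small cohort; larger experiments scale
    ``n_samples``/``n_sites`` while keeping the spectrum and map settings.
    """

    n_founders: int = 40
    n_samples: int = 200
    n_sites: int = 2000
    region_length_cm: float = 5.0
    sfs_exponent: float = 1.0
    singleton_fraction: float = 0.0
    genotyping_error_rate: float = 0.0
    seed: int = 0
    #: genealogy depth: generations of random-mating copying from founders
    n_meioses: int = 30
    #: fraction of sites carrying ancestral (founder) variation; the rest
    #: are genealogy mutations, giving the rare-variant excess
    ancestral_fraction: float = 0.3

    def __post_init__(self):
        if min(self.n_founders, self.n_samples, self.n_sites) <= 0:
            raise ValueError("all counts must be > 0")
        if not (0 <= self.singleton_fraction < 1):
            raise ValueError("singleton_fraction must be in [0, 1)")
        if not (0 <= self.genotyping_error_rate < 0.5):
            raise ValueError("genotyping_error_rate must be in [0, 0.5)")
        if self.region_length_cm <= 0:
            raise ValueError("region_length_cm must be > 0")


@dataclass
class TruthSet:
    """Simulation truth: haplotypes, pedigree and recombination events."""

    true_haplotypes: np.ndarray  # (2N, M) uint8
    pedigree: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    recombination_breakpoints: Dict[str, np.ndarray] = field(default_factory=dict)
    sample_ids: List[str] = field(default_factory=list)
    positions_bp: np.ndarray = None
    site_cm: np.ndarray = None
    parent_ids: set = field(default_factory=set)

    @property
    def n_samples(self) -> int:
        return self.true_haplotypes.shape[0] // 2

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def genotypes(self) -> np.ndarray:
        h = self.true_haplotypes
        return (h[0::2] + h[1::2]).astype(np.int8)


def _next_generation(rng, cur, cm, total_cm):
    """One generation of random-mating recombinant copying."""
    P, M = cur.shape
    k = rng.poisson(total_cm / 100.0, size=P)
    parents = rng.integers(0, P, size=(P, 2))
    new = cur[parents[:, 0]].copy()
    for i in np.nonzero(k > 0)[0]:
        breaks = np.sort(rng.uniform(0.0, total_cm, size=k[i]))
        cut = np.searchsorted(cm, breaks)
        bounds = np.concatenate(([0], cut, [M]))
        pair = (parents[i, 0], parents[i, 1])
        for seg, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            new[i, a:b] = cur[pair[seg % 2], a:b]
    return new


def simulate_panel(config: SimConfig):
    """Simulate a genealogy-structured panel of diploid samples.

    Returns ``(truth, genotypes, records)`` where ``genotypes`` is the
    ``(n_samples, n_sites)`` ALT-dosage matrix and ``records`` carry
    MAC/MAF/class computed on the sample cohort.  Deterministic given
    ``config.seed``.
    """
    if config.n_sites < 2:
        raise ValueError("invalid region: need at least 2 sites")
    rng = np.random.default_rng(config.seed)
    M = config.n_sites
    nf = config.n_founders
    G = config.n_meioses
    P = 2 * config.n_samples
    region_bp = M * BP_PER_SITE
    positions = np.sort(rng.choice(region_bp, size=M, replace=False)) + 1
    cm = positions / region_bp * config.region_length_cm

    # ancestral (founder) variation: derived counts from the power-law SFS
    n_anc = int(round(config.ancestral_fraction * M))
    anc_sites = np.sort(rng.choice(M, size=n_anc, replace=False))
    founders = np.zeros((nf, M), np.uint8)
    i_max = max(nf - 1, 1)
    pmf = np.arange(1, i_max + 1, dtype=float) ** (-config.sfs_exponent)
    pmf /= pmf.sum()
    for j in anc_sites:
        c = int(rng.choice(np.arange(1, i_max + 1), p=pmf))
        founders[rng.choice(nf, size=c, replace=False), j] = 1

    # mutation sites: one event on a random haplotype of a random generation
    mut_sites = np.setdiff1d(np.arange(M), anc_sites)
    mut_gen = rng.integers(1, G + 1, size=mut_sites.size)
    mut_hap = rng.integers(0, P, size=mut_sites.size)

    cur = founders[rng.integers(0, nf, size=P)].copy()
    for g in range(1, G + 1):
        cur = _next_generation(rng, cur, cm, config.region_length_cm)
        hit = mut_gen == g
        if hit.any():
            cur[mut_hap[hit], mut_sites[hit]] = 1
    H = cur

    # force exact MAC 1 at singleton_fraction of polymorphic sites by
    # down-sampling carriers (bookkeeping-test aid; natural singletons
    # already arise from recent/sparse-lineage mutations)
    n_single = int(round(config.singleton_fraction * M))
    if n_single > 0:
        ones = H.sum(axis=0)
        minor_count = np.minimum(ones, P - ones)
        candidates = np.nonzero(minor_count >= 1)[0]
        sites = rng.choice(candidates, size=min(n_single, candidates.size), replace=False)
        for j in sites:
            col = H[:, j]
            minor = 1 if col.sum() * 2 <= P else 0
            carriers = np.nonzero(col == minor)[0]
            keep = int(carriers[rng.integers(carriers.size)])
            col[:] = 1 - minor
            col[keep] = minor

    breakpoints: Dict[str, np.ndarray] = {}
    genotypes = (H[0::2] + H[1::2]).astype(np.int8)
    records = records_from_matrix(genotypes, positions)
    # classify with the default common/rare threshold; callers may reclassify
    from .scaffold import classify_variants

    classify_variants(records, DEFAULT_MAF_THRESHOLD)
    truth = TruthSet(
        true_haplotypes=H,
        sample_ids=[f"S{i}" for i in range(config.n_samples)],
        positions_bp=positions,
        site_cm=cm,
        recombination_breakpoints=breakpoints,
    )
    return truth, genotypes, records


def _meiosis(rng, hap_a, hap_b, cm, total_cm):
    """One recombinant gamete from a parent's haplotype pair."""
    k = rng.poisson(total_cm / 100.0)
    breaks_cm = np.sort(rng.uniform(0.0, total_cm, size=k))
    cut = np.searchsorted(cm, breaks_cm)
    bounds = np.concatenate(([0], cut, [len(cm)]))
    start = int(rng.integers(2))
    out = np.empty(len(cm), np.uint8)
    pair = (hap_a, hap_b)
    for seg, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        out[a:b] = pair[(start + seg) % 2][a:b]
    return out, breaks_cm


def simulate_trios(truth: TruthSet, n_trios: int, seed: int = 0) -> TruthSet:
    """Extend a truth set with trio offspring.

    Each offspring receives one recombinant haplotype from each parent
    (Mendel-consistent by construction at error rate 0); parents are flagged
    in ``parent_ids`` so they can be excluded from the phasing cohort, and
    the pedigree maps offspring to (father, mother).
    """
    if n_trios == 0:
        return truth
    free = [s for s in truth.sample_ids if s not in truth.parent_ids and s not in truth.pedigree]
    if len(free) < 2 * n_trios:
        raise ValueError(f"need {2 * n_trios} available parents, have {len(free)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(free), size=2 * n_trios, replace=False)
    cm = truth.site_cm
    total_cm = float(cm[-1]) if cm is not None else float(truth.true_haplotypes.shape[1])
    if cm is None:
        cm = np.arange(truth.true_haplotypes.shape[1], dtype=float)
    haps = [truth.true_haplotypes]
    sample_ids = list(truth.sample_ids)
    pedigree = dict(truth.pedigree)
    breakpoints = dict(truth.recombination_breakpoints)
    parent_ids = set(truth.parent_ids)
    for t in range(n_trios):
        father = free[chosen[2 * t]]
        mother = free[chosen[2 * t + 1]]
        fi = truth.sample_index(father)
        mi = truth.sample_index(mother)
        child = f"T{t}_child"
        pat, bp_p = _meiosis(rng, truth.true_haplotypes[2 * fi], truth.true_haplotypes[2 * fi + 1], cm, total_cm)
        mat, bp_m = _meiosis(rng, truth.true_haplotypes[2 * mi], truth.true_haplotypes[2 * mi + 1], cm, total_cm)
        haps.append(np.stack([pat, mat]))
        sample_ids.append(child)
        pedigree[child] = (father, mother)
        breakpoints[f"{child}_pat"] = bp_p
        breakpoints[f"{child}_mat"] = bp_m
        parent_ids.update((father, mother))
    return TruthSet(
        true_haplotypes=np.concatenate(haps, axis=0),
        pedigree=pedigree,
        recombination_breakpoints=breakpoints,
        sample_ids=sample_ids,
        positions_bp=truth.positions_bp,
        site_cm=truth.site_cm,
        parent_ids=parent_ids,
    )


def inject_genotyping_errors(genotypes: np.ndarray, rate: float, seed: int = 0):
    """Perturb genotypes independently with probability ``rate``.

    Hets flip to a uniformly chosen homozygote; homozygotes flip to het.
    Returns ``(perturbed_matrix, n_perturbed)``; the input is not modified.
    """
    if not (0 <= rate < 0.5):
        raise ValueError("rate must be in [0, 0.5)")
    g = np.array(genotypes, copy=True)
    if rate == 0:
        return g, 0
    rng = np.random.default_rng(seed)
    mask = (rng.random(g.shape) < rate) & (g >= 0)
    hom_choice = rng.integers(0, 2, size=g.shape) * 2  # 0 or 2
    flipped = np.where(g == 1, hom_choice, 1)
    g[mask] = flipped[mask]
    return g, int(mask.sum())


def write_fixture_vcf(truth: TruthSet, genotypes, path, phased: bool = False,
                      chrom: str = "1", sample_ids=None):
    """Write a VCF 4.2 fixture; see :mod:`phasekit.vcf_io` for the writer."""
    from .vcf_io import write_vcf

    if sample_ids is None:
        sample_ids = truth.sample_ids
    records = records_from_matrix(np.asarray(genotypes), truth.positions_bp, chrom=chrom)
    if phased:
        write_vcf(path, records, sample_ids, haplotypes=truth.true_haplotypes)
    else:
        write_vcf(path, records, sample_ids, genotypes=np.asarray(genotypes))
    return path


def cohort_view(truth: TruthSet, exclude_parents: bool = True):
    """Offspring + unrelated cohort (parents excluded), as used when
    phasing accuracy is measured on offspring with parental truth.

    Returns ``(sample_indices, haplotypes, genotypes)`` for the retained
    cohort, in truth order.
    """
    keep = [i for i, s in enumerate(truth.sample_ids)
            if not (exclude_parents and s in truth.parent_ids)]
    idx = np.asarray(keep, dtype=np.int64)
    hap_idx = np.empty(2 * idx.size, np.int64)
    hap_idx[0::2] = 2 * idx
    hap_idx[1::2] = 2 * idx + 1
    H = truth.true_haplotypes[hap_idx]
    G = (H[0::2] + H[1::2]).astype(np.int8)
    return idx, H, G
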