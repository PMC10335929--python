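"""Compound-heterozygosity screening on phased haplotypes.

A gene is compound-heterozygous in an individual when at least one
qualifying heterozygous variant lies on each of the two haplotypes
(nonidentical hits knocking out both gene copies).  Singletons are excluded
(their phase is the least reliable); rare homozygous-minor genotypes knock
out both copies on their own and are reported in a separate column rather
than counted as compound-het events.

For calibration, the expected number of compound-het individuals in a gene
under independent phase is

    sum_i 1 - (1/2)^(v_i - 1)

over individuals i with v_i >= 2 qualifying het variants, and a
randomized-phase control redraws every het orientation with a fair coin.
Enrichment of compound-het genes in external gene lists uses a two-sided
Fisher exact test with the cross-product odds ratio and Woolf log CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

EFFECT_CLASSES = ("LoF", "missense_LC", "synonymous")


@dataclass
class AnnotatedVariant:
    """Variant-to-gene annotation consumed (not generated) by the screen."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    mac: int = 0

    def __post_init__(self):
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"effect {self.effect!r} not one of {EFFECT_CLASSES}")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CompHetEvent:
    gene: str
    individual: str
    hap0_variants: List[int] = field(default_factory=list)
    hap1_variants: List[int] = field(default_factory=list)
    min_confidence: float = 1.0


def annotations_from_frame(df: pd.DataFrame) -> List[AnnotatedVariant]:
    """Build annotations from a TSV-style frame with columns
    (chrom, pos, ref, alt, gene, class) — by name when present, else by
    position."""
    cols = list(df.columns)
    names = ["chrom", "pos", "ref", "alt", "gene", "class"]
    sel = [c if c in cols else cols[i] for i, c in enumerate(names)]
    out = []
    for chrom, pos, ref, alt, gene, eff in df[sel].itertuples(index=False, name=None):
        out.append(AnnotatedVariant(chrom=str(chrom), pos=int(pos), ref=str(ref),
                                    alt=str(alt), gene=str(gene), effect=str(eff)))
    return out


def find_comphet(haplotypes: np.ndarray, records, sample_ids: Sequence[str],
                 annotations: Sequence[AnnotatedVariant], effect: str,
                 pp: Optional[Dict[Tuple[int, int], float]] = None,
                 confidence_threshold: Optional[float] = None,
                 phased_mask: Optional[np.ndarray] = None):
    """Scan a phased cohort for compound-het events of one effect class.

    Parameters
    ----------
    haplotypes : (2N, M) ALT-coded phased matrix.
    records : variant records aligned to the matrix columns (``vclass`` used
        to exclude singletons).
    annotations : joined by exact (chrom, pos, ref, alt) match; a variant
        annotated to several genes contributes once per gene.
    pp : optional per-(sample, variant) phasing confidence; calls below
        ``confidence_threshold`` are dropped before assessment.
    phased_mask : optional (N, M) boolean, False where a genotype is not
        phased; encountering an unphased het raises with the variant named.

    Returns
    -------
    events : list of :class:`CompHetEvent`.
    gene_table : per-gene DataFrame with individuals with >= 2 qualifying
        het variants, observed events, expected events under independent
        phase, and homozygous-knockout carriers (reported separately).
    """
    key_to_col = {}
    for j, r in enumerate(records):
        key_to_col[(r.chrom, r.pos, r.ref, r.alt)] = j
    genes: Dict[str, List[int]] = {}
    for ann in annotations:
        if ann.effect != effect:
            continue
        j = key_to_col.get(ann.key)
        if j is None:
            continue  # exact-allele join: unmatched annotations are dropped
        if records[j].vclass == "singleton":
            continue
        genes.setdefault(ann.gene, []).append(j)
    h0 = haplotypes[0::2]
    h1 = haplotypes[1::2]
    events: List[CompHetEvent] = []
    rows = []
    for gene in sorted(genes):
        cols = np.asarray(sorted(set(genes[gene])))
        g0 = h0[:, cols]
        g1 = h1[:, cols]
        het = g0 != g1
        hom = (g0 == 1) & (g1 == 1)
        if phased_mask is not None:
            bad = het & ~phased_mask[:, cols]
            if bad.any():
                i, j = np.argwhere(bad)[0]
                r = records[cols[j]]
                raise ValueError(
                    f"unphased heterozygote at {r.chrom}:{r.pos} in sample {sample_ids[i]}")
        qual = het.copy()
        if confidence_threshold is not None and confidence_threshold > 0 and pp is not None:
            for i, j in np.argwhere(het):
                conf = pp.get((i, int(cols[j])), 1.0)
                if conf < confidence_threshold:
                    qual[i, j] = False
        n_var = qual.sum(axis=1)
        hit0 = (qual & (g0 == 1)).sum(axis=1)
        hit1 = (qual & (g1 == 1)).sum(axis=1)
        is_event = (hit0 >= 1) & (hit1 >= 1)
        n_expected = expected_comphet(n_var[n_var >= 2])
        for i in np.nonzero(is_event)[0]:
            v0 = [int(cols[j]) for j in np.nonzero(qual[i] & (g0[i] == 1))[0]]
            v1 = [int(cols[j]) for j in np.nonzero(qual[i] & (g1[i] == 1))[0]]
            confs = [pp.get((i, v), 1.0) for v in v0 + v1] if pp else [1.0]
            events.append(CompHetEvent(gene=gene, individual=sample_ids[i],
                                       hap0_variants=v0, hap1_variants=v1,
                                       min_confidence=min(confs)))
        rows.append({
            "gene": gene,
            "n_variants": len(cols),
            "n_ind_2plus": int((n_var >= 2).sum()),
            "n_events": int(is_event.sum()),
            "expected_events": n_expected,
            "n_hom_knockout": int(hom.any(axis=1).sum()),
        })
    gene_table = pd.DataFrame(rows, columns=["gene", "n_variants", "n_ind_2plus",
                                             "n_events", "expected_events",
                                             "n_hom_knockout"])
    return events, gene_table


def expected_comphet(variant_counts) -> float:
    """Expected compound-het individuals: sum of 1 - (1/2)^(v-1).

    Individuals with fewer than two variants contribute 0.
    """
    v = np.asarray(list(variant_counts), float)
    v = v[v >= 2]
    if v.size == 0:
        return 0.0
    return float(np.sum(1.0 - 0.5 ** (v - 1.0)))


def randomize_phase(haplotypes: np.ndarray, seed: int = 0,
                    columns: Optional[np.ndarray] = None) -> np.ndarray:
    """Redraw every heterozygote's orientation with an independent fair coin.

    Homozygous genotypes (including hom-minor: both haplotypes carry the
    allele) are unchanged.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = np.array(haplotypes, copy=True)
    cols = np.arange(out.shape[1]) if columns is None else np.asarray(columns)
    h0 = out[0::2][:, cols]
    h1 = out[1::2][:, cols]
    het = h0 != h1
    swap = het & (rng.random(h0.shape) < 0.5)
    t = h0[swap]
    h0[swap] = h1[swap]
    h1[swap] = t
    out[0::2][:, np.asarray(cols)] = h0
    out[1::2][:, np.asarray(cols)] = h1
    return out


@dataclass
class FisherResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: Tuple[int, int, int, int]
    corrected: bool = False  # Haldane–Anscombe 0.5 applied to OR/CI


def enrichment_fisher(comphet_genes: Set[str], background_genes: Set[str],
                      gene_list: Set[str]) -> FisherResult:
    """Two-sided Fisher exact test of compound-het genes against a list.

    The 2x2 table crosses (compound-het vs not, within the background) with
    (in list vs not).  The odds ratio is the sample cross-product with a
    Woolf log CI; when a margin cell is zero the Haldane–Anscombe 0.5
    correction is applied to the OR and CI only (flagged) while the p-value
    stays exact.
    """
    comphet_genes = set(comphet_genes)
    background_genes = set(background_genes)
    if not comphet_genes <= background_genes:
        raise ValueError("background must contain all compound-het genes")
    if not gene_list:
        raise ValueError("empty gene list")
    non_ch = background_genes - comphet_genes
    a = len(comphet_genes & gene_list)
    b = len(comphet_genes) - a
    c = len(non_ch & gene_list)
    d = len(non_ch) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = float(np.exp(np.log(orr) - 1.959964 * se))
    hi = float(np.exp(np.log(orr) + 1.959964 * se))
    return FisherResult(odds_ratio=float(orr), ci_low=lo, ci_high=hi,
                        p_value=float(p), table=(a, b, c, d), corrected=corrected)
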