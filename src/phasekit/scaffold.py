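"""Common-variant phasing into a haplotype scaffold.

Common variants (MAF >= 0.1% by default) are phased jointly by a Gibbs
sampler: each sample in turn is re-phased conditional on the current
haplotypes of the others under a diploid Li–Stephens copying model.  The
conditioning states for a sample are picked by PBWT neighbour queries at a
grid of anchor sites, so the copying panel is small (``k_states``) but
contains the haplotypes most likely to share recent ancestry with the
target.  The final scaffold is the per-heterozygote majority orientation
over the main (post burn-in) iterations.

The switch probability between adjacent scaffold sites is

    rho_m = 1 - exp(-0.04 * n_eff * d_cm / K)

with ``d_cm`` the genetic distance and ``K`` the number of conditioning
states, and the per-site copying error (mismatch emission) is ``theta``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import pbwt as _pbwt
from ._kernels import diploid_ffbs
from .variants import (COMMON, DEFAULT_MAF_THRESHOLD, MONOMORPHIC, RARE,
                       SINGLETON, VariantRecord, compute_mac_maf)

logger = logging.getLogger(__name__)


@dataclass
class LSParams:
    """Li–Stephens / Gibbs sampler parameters.

    ``n_eff`` is the effective population size scaling recombination,
    ``theta`` the copying mismatch probability, ``k_states`` the size of the
    per-sample conditioning panel.  Defaults follow conventional
    Li–Stephens practice; all are configurable.
    """

    n_eff: float = 15_000.0
    theta: float = 1e-4
    k_states: int = 16
    n_burnin: int = 5
    n_main: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_eff <= 0:
            raise ValueError("n_eff must be > 0")
        if not (0 < self.theta < 0.5):
            raise ValueError("theta must be in (0, 0.5)")
        if self.k_states < 2:
            raise ValueError("k_states must be >= 2")
        if self.n_burnin < 1 or self.n_main < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class HaplotypeScaffold:
    """Phased common-variant haplotypes with genetic-map coordinates."""

    haplotypes: np.ndarray  # (2N, M_common) uint8
    sample_ids: List[str]
    records: List[VariantRecord]
    site_cm: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def check_consistency(self, genotypes: np.ndarray) -> bool:
        return bool(np.array_equal(self.genotypes(), np.asarray(genotypes, dtype=np.int8)))


def classify_variants(records, maf_threshold: float = DEFAULT_MAF_THRESHOLD,
                      genotypes: Optional[np.ndarray] = None):
    """Assign common/rare/singleton classes in place; returns the classes.

    ``singleton`` is MAC == 1 regardless of cohort size; ``common`` is
    MAF >= threshold (boundary inclusive); everything else is ``rare``.
    When ``genotypes`` is given, stored MACs are validated against it.
    """
    if genotypes is not None:
        mac, _, _, _ = compute_mac_maf(genotypes)
        for j, r in enumerate(records):
            if r.mac != mac[j]:
                raise ValueError(
                    f"MAC inconsistent with genotypes at {r.chrom}:{r.pos} "
                    f"(record {r.mac}, genotypes {int(mac[j])})"
                )
    classes = []
    for r in records:
        if r.mac == 0:
            r.vclass = MONOMORPHIC
        elif r.mac == 1:
            r.vclass = SINGLETON
        elif r.maf < maf_threshold:
            r.vclass = RARE
        else:
            r.vclass = COMMON
        classes.append(r.vclass)
    return classes


def initialize_haplotypes(genotypes, records, site_cm, sample_ids=None, seed: int = 0) -> HaplotypeScaffold:
    """Random genotype-consistent initialisation.

    Homozygous sites are fixed; each heterozygote is oriented uniformly at
    random.  Missing genotypes (< 0) are imputed to the major allele with a
    logged count.
    """
    g = np.array(genotypes, dtype=np.int8, copy=True)
    n_missing = int((g < 0).sum())
    if n_missing:
        _, _, minor_is_alt, _ = compute_mac_maf(g)
        major = np.where(minor_is_alt, 0, 2).astype(np.int8)
        miss_r, miss_c = np.nonzero(g < 0)
        g[miss_r, miss_c] = major[miss_c]
        logger.info("imputed %d missing genotypes to the major allele", n_missing)
    rng = np.random.default_rng(seed)
    N, M = g.shape
    H = np.zeros((2 * N, M), np.uint8)
    hom_alt = g == 2
    H[0::2][hom_alt] = 1
    H[1::2][hom_alt] = 1
    het = g == 1
    flip = rng.integers(0, 2, size=g.shape, dtype=np.uint8)
    H[0::2][het] = flip[het]
    H[1::2][het] = 1 - flip[het]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(N)]
    return HaplotypeScaffold(haplotypes=H, sample_ids=list(sample_ids),
                             records=list(records), site_cm=np.asarray(site_cm, float))


def recombination_probs(site_cm: np.ndarray, n_eff: float, k_states: int) -> np.ndarray:
    d = np.maximum(np.diff(np.asarray(site_cm, float)), 1e-7)
    return -np.expm1(-0.04 * n_eff * d / k_states)


def _anchor_sites(M: int, n_anchors: int = 16) -> np.ndarray:
    n = min(n_anchors, M)
    return np.unique(np.linspace(0, M - 1, n).round().astype(int))


def select_states(index_fwd: _pbwt.PbwtIndex, anchors, sample: int, k_states: int,
                  n_haps: int, per_anchor: int = 2) -> np.ndarray:
    """PBWT conditioning panel for one sample.

    At each anchor site the nearest sorted-order neighbours of both target
    haplotypes are collected, and the panel is filled round-robin across
    anchors (nearest neighbour of every anchor first).  The round-robin fill
    guarantees every region of the chromosome contributes its locally best
    matches, which matters more than global similarity ranking: a target is
    a mosaic, and each mosaic segment needs its own copying source in the
    panel.  The sample's own haplotypes are excluded.
    """
    own = (2 * sample, 2 * sample + 1)
    buckets = []
    for a in anchors:
        inv = index_fwd.inverse(int(a))
        order = index_fwd.prefix[int(a)]
        for hap in own:
            p = int(inv[hap])
            cand = []
            up, down = p - 1, p + 1
            while len(cand) < per_anchor and (up >= 0 or down < n_haps):
                for q in (up, down):
                    if 0 <= q < n_haps:
                        c = int(order[q])
                        if c != own[0] and c != own[1]:
                            cand.append(c)
                up -= 1
                down += 1
            buckets.append(cand)
    out: list = []
    seen = set()
    depth = 0
    while len(out) < k_states:
        added = False
        for b in buckets:
            if depth < len(b) and b[depth] not in seen:
                seen.add(b[depth])
                out.append(b[depth])
                added = True
                if len(out) >= k_states:
                    break
        depth += 1
        if not added and depth > per_anchor:
            break
    if len(out) < 2:
        pool = [h for h in range(n_haps) if h not in own]
        if len(pool) < 2:
            raise ValueError("need at least 2 conditioning haplotypes")
        out = pool[:k_states]
    return np.asarray(out, np.int64)


def gibbs_update_sample(scaffold: HaplotypeScaffold, sample: int,
                        index_fwd: _pbwt.PbwtIndex, params: LSParams, rng,
                        genotype: Optional[np.ndarray] = None,
                        anchors: Optional[np.ndarray] = None,
                        greedy: bool = False):
    """Resample one sample's haplotype pair from the diploid LS posterior.

    Returns ``(h0, h1, het_prob, states)`` where ``het_prob`` is the
    path-conditional probability that hap0 carries ALT at each het (-1 at
    homozygous sites).  With ``greedy=True`` the backward pass decodes the
    most probable path instead of sampling (used for polish sweeps).  The
    scaffold itself is not modified.
    """
    H = scaffold.haplotypes
    M = scaffold.n_sites
    if genotype is None:
        genotype = (H[2 * sample] + H[2 * sample + 1]).astype(np.int8)
    if anchors is None:
        anchors = _anchor_sites(M)
    states = select_states(index_fwd, anchors, sample, params.k_states, H.shape[0])
    if states.size < 2:
        raise ValueError("need at least 2 conditioning haplotypes")
    panel = np.ascontiguousarray(H[states])
    rho = recombination_probs(scaffold.site_cm, params.n_eff, states.size)
    h0, h1, het_prob = diploid_ffbs(panel, genotype, rho, params.theta,
                                    rng.random(M), rng.random(M), greedy)
    return h0, h1, het_prob, states


def _align_pair(h0, h1, cur0, het_mask):
    """Flip the sampled pair if it disagrees with the current hap0 at a
    majority of hets (keeps hap labels stable across Gibbs iterations)."""
    agree = int((h0[het_mask] == cur0[het_mask]).sum())
    n = int(het_mask.sum())
    return agree * 2 >= n


def phase_common(genotypes, records, site_cm=None, params: Optional[LSParams] = None,
                 sample_ids=None, maf_threshold: float = DEFAULT_MAF_THRESHOLD):
    """Phase the common variants of a cohort into a scaffold.

    Parameters
    ----------
    genotypes : (N, M) dosage matrix over *all* variants (records aligned);
        the common subset (MAF >= ``maf_threshold``) is selected internally.
    site_cm : genetic coordinates per variant (site ordinals if ``None``).

    Returns
    -------
    scaffold : :class:`HaplotypeScaffold` over the common sites.
    het_posterior : (N, M_common) float matrix; at hets, the vote fraction
        for the consensus orientation (in [0.5, 1]); NaN elsewhere.
    common_idx : indices of the common sites within the input records.
    """
    params = params or LSParams()
    g = np.asarray(genotypes, dtype=np.int8)
    N, M = g.shape
    if N < 2:
        raise ValueError("need at least 2 samples")
    if site_cm is None:
        site_cm = np.arange(M, dtype=float)
    site_cm = np.asarray(site_cm, float)
    classes = [r.vclass for r in records]
    if any(c is None for c in classes):
        classes = classify_variants(records, maf_threshold)
    common_idx = np.asarray([j for j, c in enumerate(classes) if c == COMMON], np.int64)
    if common_idx.size == 0:
        logger.warning("no polymorphic common sites: nothing to phase")
        empty = HaplotypeScaffold(np.zeros((2 * N, 0), np.uint8),
                                  sample_ids=list(sample_ids or [f"S{i}" for i in range(N)]),
                                  records=[], site_cm=np.empty(0))
        return empty, np.empty((N, 0)), common_idx
    gc = np.ascontiguousarray(g[:, common_idx])
    cm = site_cm[common_idx]
    recs = [records[j] for j in common_idx]
    rng = np.random.default_rng(params.seed)
    scaffold = initialize_haplotypes(gc, recs, cm, sample_ids,
                                     seed=int(rng.integers(2**31 - 1)))
    H = scaffold.haplotypes
    Mc = scaffold.n_sites
    het = gc == 1
    votes = np.zeros((N, Mc))
    n_votes = 0
    anchors = _anchor_sites(Mc)
    order = np.arange(N)
    # sweep schedule: burn-in sampling, then main sampling sweeps feeding
    # the orientation votes, then greedy polish sweeps (most probable path
    # instead of a draw) that stop re-injecting sampling noise into the
    # panel and settle it into a posterior mode
    n_total = params.n_burnin + params.n_main
    n_polish = (params.n_main + 1) // 2
    greedy_from = n_total - n_polish
    for sweep in range(n_total):
        greedy = sweep >= greedy_from
        index_fwd = _pbwt.build_pbwt(H, "forward", cm)
        for a in anchors:  # warm the inverse-permutation cache once
            index_fwd.inverse(int(a))
        rng.shuffle(order)
        for s in order:
            h0, h1, _, _ = gibbs_update_sample(scaffold, int(s), index_fwd, params, rng,
                                               genotype=gc[s], anchors=anchors,
                                               greedy=greedy)
            hm = het[s]
            if hm.any() and not _align_pair(h0, h1, H[2 * s], hm):
                h0, h1 = h1, h0
            H[2 * s] = h0
            H[2 * s + 1] = h1
            if params.n_burnin <= sweep < greedy_from:
                votes[s, hm] += h0[hm]
        if params.n_burnin <= sweep < greedy_from:
            n_votes += 1
    # per-het orientation posterior: agreement of the main-phase sampled
    # orientations with the final (polished) haplotypes
    frac = votes / max(n_votes, 1)
    agree = np.where(H[0::2] == 1, frac, 1.0 - frac)
    het_posterior = np.full((N, Mc), np.nan)
    het_posterior[het] = np.maximum(agree[het], 1.0 - agree[het])
    assert scaffold.check_consistency(gc)
    return scaffold, het_posterior, common_idx


def ligate_chunks(chunks: List[HaplotypeScaffold]) -> HaplotypeScaffold:
    """Ligate chunk scaffolds that share overlapping buffer sites.

    Chunks must be position-sorted and adjacent chunks must overlap.  For
    each sample, a chunk is globally flipped when the majority of shared
    buffer heterozygotes disagree in orientation with the running scaffold;
    the output switches source chunks at the buffer midpoint.  Samples with
    no shared het in a buffer keep an arbitrary relative orientation
    (counted and logged).
    """
    if not chunks:
        raise ValueError("no chunks")
    out = chunks[0]
    H = out.haplotypes.copy()
    recs = list(out.records)
    cm = list(out.site_cm)
    pos = [r.pos for r in recs]
    n_arbitrary = 0
    for nxt in chunks[1:]:
        nxt_pos = [r.pos for r in nxt.records]
        shared = sorted(set(pos) & set(nxt_pos))
        if not shared:
            raise ValueError("non-overlapping chunks cannot be ligated")
        ia = {p: i for i, p in enumerate(pos)}
        ib = {p: i for i, p in enumerate(nxt_pos)}
        a_idx = np.asarray([ia[p] for p in shared])
        b_idx = np.asarray([ib[p] for p in shared])
        Hb = nxt.haplotypes.copy()
        N = H.shape[0] // 2
        for s in range(N):
            a0 = H[2 * s, a_idx]
            a1 = H[2 * s + 1, a_idx]
            b0 = Hb[2 * s, b_idx]
            hets = a0 != a1
            if not hets.any():
                n_arbitrary += 1
                continue
            agree = int((a0[hets] == b0[hets]).sum())
            if 2 * agree < int(hets.sum()):
                Hb[2 * s], Hb[2 * s + 1] = Hb[2 * s + 1].copy(), Hb[2 * s].copy()
        # switch chunks at the buffer midpoint
        mid = shared[len(shared) // 2]
        keep_a = [i for i, p in enumerate(pos) if p <= mid]
        keep_b = [i for i, p in enumerate(nxt_pos) if p > mid]
        H = np.concatenate([H[:, keep_a], Hb[:, keep_b]], axis=1)
        recs = [recs[i] for i in keep_a] + [nxt.records[i] for i in keep_b]
        cm = [cm[i] for i in keep_a] + [nxt.site_cm[i] for i in keep_b]
        pos = [r.pos for r in recs]
    if n_arbitrary:
        logger.warning("%d sample-buffers had no shared het; orientation arbitrary", n_arbitrary)
    return HaplotypeScaffold(haplotypes=H, sample_ids=list(out.sample_ids),
                             records=recs, site_cm=np.asarray(cm, float))
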