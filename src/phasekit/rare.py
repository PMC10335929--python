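"""Rare-heterozygote phasing onto the common-variant scaffold.

Each rare heterozygote is phased independently of the others, given the
scaffold: an individualized conditioning set is assembled from (1) a general
PBWT long-match pass around the variant's flanking common sites and (2) a
carrier-restricted pass guaranteeing minor-allele carriers are present.
Heterozygous conditioning samples contribute the minor allele on *both*
haplotypes (forced homozygosity: their own phase at the rare site is
unknown).  A haploid Li–Stephens forward-backward then imputes, for each
target haplotype, the probability of carrying the minor allele; the
posterior copying probabilities are read at the two flanking common sites
and averaged.  The two haploid probabilities are combined under the
heterozygosity constraint (exactly one haplotype carries the minor allele):

    P(minor on hap0) = p0 (1 - p1) / (p0 (1 - p1) + p1 (1 - p0))

Singletons carry no carrier information; they are phased by the
coalescent-inspired shortest-match rule: the minor allele goes to the target
haplotype whose longest shared segment through the site is *shorter* (older
local common ancestor, hence more time for a new mutation), with confidence
fixed at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import pbwt as _pbwt
from ._kernels import haploid_forward_backward, longest_match_through
from .scaffold import HaplotypeScaffold, LSParams, recombination_probs
from .variants import COMMON, MONOMORPHIC, RARE, SINGLETON

logger = logging.getLogger(__name__)

HET = 1
HOM_MINOR = 2

PROB_CLAMP = 1e-12


@dataclass
class SparseRareStore:
    """Sparse carrier index over rare + singleton variants.

    Only minor-allele carriers are stored, doubly indexed by variant and by
    sample; ``anchor`` maps each rare variant to the scaffold ordinals of
    its two closest flanking common sites (edge variants anchor twice to the
    single nearest).
    """

    by_variant: Dict[int, List[Tuple[int, int]]]  # var -> [(sample, HET|HOM_MINOR)]
    by_sample: Dict[int, List[Tuple[int, int]]]  # sample -> [(var, HET|HOM_MINOR)]
    anchor: Dict[int, Tuple[int, int]]  # var -> (left, right) scaffold ordinals
    classes: Dict[int, str]  # var -> rare | singleton
    minor_is_alt: Dict[int, bool]
    n_samples: int = 0
    n_variants: int = 0

    @property
    def n_stored(self) -> int:
        return sum(len(v) for v in self.by_variant.values())


@dataclass
class ConditioningSet:
    """Haplotypes conditioning one rare-het phasing, with forced alleles."""

    haps: np.ndarray  # haplotype ordinals
    alleles: np.ndarray  # 0 major / 1 minor per haplotype at the rare site
    provenance: np.ndarray  # "match" | "carrier" per haplotype

    def __post_init__(self):
        if self.alleles.size and not (self.alleles.any() and (self.alleles == 0).any()):
            raise ValueError("conditioning set must be polymorphic at the rare variant")


@dataclass
class PhaseCall:
    """Phased orientation of one rare heterozygote."""

    sample: int
    variant: int
    orientation: int  # 0: minor on hap0, 1: minor on hap1
    confidence: float  # in [0.5, 1]
    is_singleton: bool = False
    tie_broken: bool = False

    def __post_init__(self):
        if not (0.5 - 1e-12 <= self.confidence <= 1.0 + 1e-12):
            raise ValueError(f"confidence {self.confidence} outside [0.5, 1]")


def build_sparse_store(genotypes, records, classes=None,
                       common_positions=None, positions=None) -> SparseRareStore:
    """Index minor-allele carriers of every rare/singleton variant.

    ``common_positions``/``positions`` are the bp positions of the scaffold
    sites and of all variants (defaults come from the records); anchors are
    the scaffold ordinals flanking each rare variant's position.
    """
    g = np.asarray(genotypes)
    if classes is None:
        classes = [r.vclass for r in records]
    if positions is None:
        positions = np.asarray([r.pos for r in records])
    if common_positions is None:
        common_positions = np.asarray(
            [r.pos for r, c in zip(records, classes) if c == COMMON])
    by_variant: Dict[int, List[Tuple[int, int]]] = {}
    by_sample: Dict[int, List[Tuple[int, int]]] = {}
    anchor: Dict[int, Tuple[int, int]] = {}
    vclasses: Dict[int, str] = {}
    minor_is_alt: Dict[int, bool] = {}
    Mc = len(common_positions)
    for j, (r, c) in enumerate(zip(records, classes)):
        if c not in (RARE, SINGLETON):
            continue
        mia = bool(r.minor_is_alt)
        gm = g[:, j] if mia else 2 - g[:, j]
        carriers = np.nonzero(gm >= 1)[0]
        if carriers.size == 0:
            raise ValueError(f"rare variant {r.chrom}:{r.pos} has no carriers (MAC bookkeeping bug)")
        entries = [(int(s), HOM_MINOR if gm[s] == 2 else HET) for s in carriers]
        by_variant[j] = entries
        for s, kind in entries:
            by_sample.setdefault(s, []).append((j, kind))
        if Mc == 0:
            raise ValueError("no common scaffold sites to anchor rare variants")
        right = int(np.searchsorted(common_positions, r.pos))
        left = right - 1
        if left < 0:
            left = right = 0
        elif right >= Mc:
            left = right = Mc - 1
        anchor[j] = (left, right)
        vclasses[j] = c
        minor_is_alt[j] = mia
    return SparseRareStore(by_variant=by_variant, by_sample=by_sample,
                           anchor=anchor, classes=vclasses,
                           minor_is_alt=minor_is_alt,
                           n_samples=g.shape[0], n_variants=g.shape[1])


def build_conditioning_set(variant: int, sample: int, scaffold: HaplotypeScaffold,
                           index_fwd: _pbwt.PbwtIndex, index_bwd: _pbwt.PbwtIndex,
                           store: SparseRareStore, k_each_side: int = 4,
                           max_states: int = 16) -> ConditioningSet:
    """Union of the long-match pass and the carrier-restricted pass.

    Alleles at the rare variant are assigned per conditioning *sample*:
    carriers (het or hom-minor) contribute the minor allele on both
    haplotypes (forced homozygosity), all others the major allele.  The
    result is guaranteed polymorphic.
    """
    left, right = store.anchor[variant]
    carriers = [(s, k) for s, k in store.by_variant[variant] if s != sample]
    if not carriers:
        raise _pbwt.SingletonRouteError(
            f"variant {variant}: no carrier besides the target; use the singleton model")
    carrier_set = {s for s, _ in carriers}
    own = (2 * sample, 2 * sample + 1)
    general: Dict[int, float] = {}
    for hap in own:
        for h, m in _pbwt.matches_at(index_fwd, index_bwd, left, hap,
                                     k_each_side, right_site=right).items():
            if h not in own:
                general[h] = max(general.get(h, 0.0), m.total_cm)
    restricted = set()
    for hap in own:
        restricted.update(_pbwt.restricted_matches(
            index_fwd, index_bwd, left, hap, sorted(carrier_set),
            k_each_side=max(2, k_each_side // 2), right_site=right))
    restricted -= set(own)
    haps: List[int] = []
    prov: List[str] = []
    for h in sorted(restricted):
        haps.append(h)
        prov.append("carrier")
    # fill with the longest general matches up to the cap
    for h, _ in sorted(general.items(), key=lambda kv: (-kv[1], kv[0])):
        if len(haps) >= max_states:
            break
        if h not in restricted:
            haps.append(h)
            prov.append("match")
    alleles = np.asarray([1 if (h // 2) in carrier_set else 0 for h in haps], np.int8)
    if not (alleles == 0).any():
        # every neighbour is a carrier: add the nearest non-carrier in sorted
        # order at the left flank to restore polymorphism
        inv = index_fwd.inverse(left)
        order = index_fwd.prefix[left]
        p = int(inv[own[0]])
        for d in range(1, index_fwd.n_haps):
            for q in (p - d, p + d):
                if 0 <= q < index_fwd.n_haps:
                    h = int(order[q])
                    if h not in own and (h // 2) not in carrier_set:
                        haps.append(h)
                        prov.append("match")
                        alleles = np.append(alleles, np.int8(0))
                        break
            else:
                continue
            break
    return ConditioningSet(haps=np.asarray(haps, np.int64), alleles=alleles,
                           provenance=np.asarray(prov))


def impute_allele_prob(target_hap: int, cset: ConditioningSet,
                       anchors: Tuple[int, int], scaffold: HaplotypeScaffold,
                       params: Optional[LSParams] = None,
                       gamma_out: Optional[list] = None) -> float:
    """Probability that ``target_hap`` carries the minor allele.

    Haploid Li–Stephens forward-backward over the scaffold with the
    conditioning haplotypes as states; state posteriors at the two anchor
    sites are averaged with equal weight and contracted against the forced
    allele assignment.
    """
    params = params or LSParams()
    H = np.ascontiguousarray(scaffold.haplotypes[cset.haps])
    obs = np.ascontiguousarray(scaffold.haplotypes[target_hap])
    K = H.shape[0]
    rho = recombination_probs(scaffold.site_cm, params.n_eff, K)
    gamma = haploid_forward_backward(H, obs, rho, params.theta)
    left, right = anchors
    g = 0.5 * (gamma[left] + gamma[right])
    if gamma_out is not None:
        gamma_out.append(gamma)
    p = float(g @ (cset.alleles == 1))
    if not np.isfinite(p):
        raise FloatingPointError("degenerate copying posterior")
    return min(max(p, PROB_CLAMP), 1.0 - PROB_CLAMP)


def phase_rare_het(p0: float, p1: float, sample: int = -1, variant: int = -1) -> PhaseCall:
    """Combine the two haploid minor-allele probabilities into a phase call.

    Conditions the independent imputation probabilities on the constraint
    that exactly one target haplotype carries the minor allele.
    """
    p0 = min(max(p0, PROB_CLAMP), 1.0 - PROB_CLAMP)
    p1 = min(max(p1, PROB_CLAMP), 1.0 - PROB_CLAMP)
    num = p0 * (1.0 - p1)
    den = num + p1 * (1.0 - p0)
    p_hap0 = num / den
    orientation = 0 if p_hap0 >= 0.5 else 1
    confidence = max(p_hap0, 1.0 - p_hap0)
    return PhaseCall(sample=sample, variant=variant, orientation=orientation,
                     confidence=min(confidence, 1.0), tie_broken=(p0 == p1))


def phase_singleton(variant: int, sample: int, scaffold: HaplotypeScaffold,
                    store: SparseRareStore, rng,
                    indices: Optional[tuple] = None,
                    window: int = 400) -> PhaseCall:
    """Shortest-match singleton phasing with confidence exactly 0.5.

    For each target haplotype the longest shared segment through the anchor
    is found by exact scan over all other haplotypes; the minor allele is
    assigned to the haplotype with the *shorter* longest match.  Equal
    lengths are broken by a seeded coin flip and flagged.
    """
    if scaffold.haplotypes.shape[0] < 4:
        raise ValueError("singleton phasing needs at least 2 other haplotypes")
    left, right = store.anchor[variant]
    site = left  # anchor the scan at the left flank of the singleton
    h0, h1 = 2 * sample, 2 * sample + 1
    cm = np.ascontiguousarray(scaffold.site_cm, dtype=np.float64)
    _, l0 = longest_match_through(scaffold.haplotypes, cm, site, h0, h1, -1)
    _, l1 = longest_match_through(scaffold.haplotypes, cm, site, h1, h0, -1)
    if l0 == l1:
        orientation = int(rng.integers(2))
        tie = True
    else:
        orientation = 0 if l0 < l1 else 1
        tie = False
    return PhaseCall(sample=sample, variant=variant, orientation=orientation,
                     confidence=0.5, is_singleton=True, tie_broken=tie)


def phase_all_rare(scaffold: HaplotypeScaffold, store: SparseRareStore,
                   params: Optional[LSParams] = None, seed: int = 0,
                   k_each_side: int = 4, max_states: int = 16):
    """Phase every rare heterozygote and singleton onto the scaffold.

    Returns ``(calls, rare_haplotypes)`` where ``rare_haplotypes`` is a
    ``(2N, n_variants)`` minor-allele indicator matrix over *all* variants
    indexed by the store (scaffold columns are left zero — common sites live
    in the scaffold); hom-minor genotypes are phased trivially (minor on
    both haplotypes).  Deterministic given ``seed``.
    """
    params = params or LSParams()
    rng = np.random.default_rng(seed)
    index_fwd = _pbwt.build_pbwt(scaffold.haplotypes, "forward", scaffold.site_cm)
    index_bwd = _pbwt.build_pbwt(scaffold.haplotypes, "backward", scaffold.site_cm)
    calls: List[PhaseCall] = []
    n_hap = scaffold.haplotypes.shape[0]
    rare_h = np.zeros((n_hap, store.n_variants), np.uint8)
    for variant in sorted(store.by_variant):
        vclass = store.classes[variant]
        entries = store.by_variant[variant]
        for s, kind in entries:
            if kind == HOM_MINOR:
                rare_h[2 * s, variant] = 1
                rare_h[2 * s + 1, variant] = 1
                continue
            if vclass == SINGLETON:
                call = phase_singleton(variant, s, scaffold, store, rng)
            else:
                cset = build_conditioning_set(variant, s, scaffold, index_fwd,
                                              index_bwd, store, k_each_side,
                                              max_states)
                anchors = store.anchor[variant]
                p0 = impute_allele_prob(2 * s, cset, anchors, scaffold, params)
                p1 = impute_allele_prob(2 * s + 1, cset, anchors, scaffold, params)
                call = phase_rare_het(p0, p1, sample=s, variant=variant)
                if call.tie_broken:
                    call.orientation = int(rng.integers(2))
            calls.append(call)
            rare_h[2 * s + call.orientation, variant] = 1
    return calls, rare_h


def assemble_phased_matrix(scaffold: HaplotypeScaffold, store: SparseRareStore,
                           rare_haplotypes: np.ndarray, records,
                           common_idx: np.ndarray) -> np.ndarray:
    """Full ALT-coded phased haplotype matrix over all input variants.

    Common columns come from the scaffold; rare/singleton columns from the
    phasing calls (converted back from minor-allele to ALT coding);
    monomorphic columns are constant.
    """
    n_hap = scaffold.haplotypes.shape[0]
    M = len(records)
    out = np.zeros((n_hap, M), np.uint8)
    out[:, common_idx] = scaffold.haplotypes
    for j, r in enumerate(records):
        if r.vclass in (RARE, SINGLETON):
            minor = rare_haplotypes[:, j]
            out[:, j] = minor if store.minor_is_alt[j] else 1 - minor
        elif r.vclass == MONOMORPHIC:
            out[:, j] = 0 if r.minor_is_alt else 1
    return out
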