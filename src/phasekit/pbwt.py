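"""Positional Burrows–Wheeler transform over a phased haplotype scaffold.

The PBWT keeps, at every scaffold site, the haplotypes sorted by reversed
prefix together with divergence values (start of the match between sorted
neighbours).  Haplotypes sharing long segments ending at a site are adjacent
in that ordering, so long-match queries reduce to inspecting a handful of
neighbours of the target — this is what makes individualized conditioning
sets affordable for every rare heterozygote.

Two indexes are used together: a forward index (matches extending leftwards,
ending at the queried site) and a backward index built on the site-reversed
scaffold (matches extending rightwards).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from ._kernels import pbwt_build_arrays


class SingletonRouteError(ValueError):
    """Raised when a carrier-restricted query has no carriers: the variant
    is a singleton and must be phased by the shortest-match model."""


@dataclass
class Match:
    """A conditioning candidate returned by a match query."""

    hap: int
    left_cm: float = 0.0
    right_cm: float = 0.0

    @property
    def total_cm(self) -> float:
        return self.left_cm + self.right_cm


@dataclass
class PbwtIndex:
    prefix: np.ndarray  # (M, n_hap) int32 sorted orderings
    div: np.ndarray  # (M, n_hap) int32 divergence values
    direction: str  # "forward" | "backward"
    site_cm: np.ndarray  # cM coordinate per scaffold site (original order)
    n_haps: int = 0
    _inv_cache: Dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.n_haps = self.prefix.shape[1]

    @property
    def n_sites(self) -> int:
        return self.prefix.shape[0]

    def inverse(self, site: int) -> np.ndarray:
        """Position of each haplotype in the sorted order at ``site``."""
        inv = self._inv_cache.get(site)
        if inv is None:
            inv = np.empty(self.n_haps, np.int32)
            inv[self.prefix[site]] = np.arange(self.n_haps, dtype=np.int32)
            self._inv_cache[site] = inv
        return inv

    def clear_cache(self) -> None:
        self._inv_cache.clear()


def build_pbwt(haplotypes, direction: str = "forward", site_cm=None) -> PbwtIndex:
    """Build a PBWT index over a binary haplotype matrix.

    Parameters
    ----------
    haplotypes:
        ``(n_hap, n_site)`` binary matrix, or an object exposing a
        ``haplotypes`` attribute and ``site_cm`` (a scaffold).
    direction:
        ``"forward"`` processes sites left to right; ``"backward"`` is the
        forward construction on the site-reversed matrix (arrays stored in
        reversed coordinates).
    site_cm:
        Genetic coordinates per site; defaults to the scaffold's, else the
        site ordinal (match lengths then count sites).
    """
    if hasattr(haplotypes, "haplotypes"):
        if site_cm is None:
            site_cm = getattr(haplotypes, "site_cm", None)
        haplotypes = haplotypes.haplotypes
    H = np.ascontiguousarray(np.asarray(haplotypes, dtype=np.uint8))
    if H.ndim != 2 or H.shape[0] < 1 or H.shape[1] < 1:
        raise ValueError("scaffold must be a non-empty 2-D haplotype matrix")
    if np.any(H > 1):
        raise ValueError("non-binary allele in scaffold")
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    if site_cm is None:
        site_cm = np.arange(H.shape[1], dtype=float)
    site_cm = np.asarray(site_cm, dtype=float)
    if direction == "backward":
        H = np.ascontiguousarray(H[:, ::-1])
    prefix, div = pbwt_build_arrays(H)
    return PbwtIndex(prefix=prefix, div=div, direction=direction, site_cm=site_cm)


def _neighbour_matches(index: PbwtIndex, site: int, target_hap: int, k_each_side: int):
    """Neighbours of ``target_hap`` in the sorted order at ``site``.

    Yields ``(hap, match_start)`` where ``match_start`` is the first site
    (in the index's own coordinates) of the match with the target; the match
    covers ``[match_start, site]``.  Walking outwards, the running maximum of
    divergence values gives the match start, so nearer neighbours never have
    shorter matches than farther ones on the same side (Durbin adjacency).
    """
    order = index.prefix[site]
    div = index.div[site]
    n = index.n_haps
    p = int(index.inverse(site)[target_hap])
    out = []
    # upwards (towards index 0): match start with neighbour j is
    # max(div[j+1 .. p])
    start = 0
    j = p
    for _ in range(k_each_side):
        if j == 0:
            break
        start = max(start, int(div[j]))
        j -= 1
        out.append((int(order[j]), start))
    # downwards: match start with neighbour j is max(div[p+1 .. j])
    start = 0
    j = p
    for _ in range(k_each_side):
        if j == n - 1:
            break
        j += 1
        start = max(start, int(div[j]))
        out.append((int(order[j]), start))
    return out


def _length_cm_forward(index: PbwtIndex, site: int, match_start: int) -> float:
    if match_start > site:
        return 0.0
    return float(index.site_cm[site] - index.site_cm[match_start])


def _length_cm_backward(index: PbwtIndex, rev_site: int, match_start: int) -> float:
    # reversed coordinates: site j (reversed) is original M-1-j
    M = index.n_sites
    if match_start > rev_site:
        return 0.0
    orig_right = M - 1 - match_start
    orig_left = M - 1 - rev_site
    return float(index.site_cm[orig_right] - index.site_cm[orig_left])


def matches_at(
    index_fwd: PbwtIndex,
    index_bwd: PbwtIndex,
    site: int,
    target_hap: int,
    k_each_side: int = 4,
    right_site: Optional[int] = None,
):
    """Long-match candidates for ``target_hap`` centred at ``site``.

    The forward index is interrogated at ``site`` (the left flank of the
    query position) giving leftward match lengths, the backward index at
    ``right_site`` (default ``site + 1``, the right flank) giving rightward
    lengths.  Forward and backward candidates are merged by union; a
    haplotype found in both carries both flanking lengths.

    Returns a dict ``hap -> Match`` (empty for ``k_each_side == 0``).
    """
    M = index_fwd.n_sites
    if not (0 <= site < M):
        raise ValueError(f"site {site} out of range")
    if index_bwd.direction != "backward" or index_fwd.direction != "forward":
        raise ValueError("pass (forward, backward) indices in that order")
    if right_site is None:
        right_site = min(site + 1, M - 1)
    out: Dict[int, Match] = {}
    if k_each_side == 0:
        return out
    for hap, start in _neighbour_matches(index_fwd, site, target_hap, k_each_side):
        m = out.setdefault(hap, Match(hap=hap))
        m.left_cm = max(m.left_cm, _length_cm_forward(index_fwd, site, start))
    rev = M - 1 - right_site
    for hap, start in _neighbour_matches(index_bwd, rev, target_hap, k_each_side):
        m = out.setdefault(hap, Match(hap=hap))
        m.right_cm = max(m.right_cm, _length_cm_backward(index_bwd, rev, start))
    return out


def restricted_matches(
    index_fwd: PbwtIndex,
    index_bwd: PbwtIndex,
    site: int,
    target_hap: int,
    carrier_samples,
    k_each_side: int = 2,
    right_site: Optional[int] = None,
):
    """Nearest carrier haplotypes in sorted order at the flanking sites.

    ``carrier_samples`` are sample ordinals (haplotypes ``2s`` and
    ``2s + 1``); the target's own sample is excluded by the caller.  The
    search walks the prefix arrays restricted to carrier haplotypes, so with
    at least one carrier the result is guaranteed non-empty; with exactly
    one carrier sample both its haplotypes are returned regardless of
    distance.
    """
    carrier_samples = np.asarray(list(carrier_samples), dtype=np.int64)
    if carrier_samples.size == 0:
        raise SingletonRouteError(
            "no carrier samples: variant is a singleton, use the singleton model"
        )
    carrier_haps = np.empty(2 * carrier_samples.size, np.int64)
    carrier_haps[0::2] = 2 * carrier_samples
    carrier_haps[1::2] = 2 * carrier_samples + 1
    M = index_fwd.n_sites
    if right_site is None:
        right_site = min(site + 1, M - 1)
    out = set()
    for index, qsite in ((index_fwd, site), (index_bwd, M - 1 - right_site)):
        inv = index.inverse(qsite)
        pos = inv[carrier_haps]
        p = int(inv[target_hap])
        order = np.argsort(pos, kind="stable")
        sorted_pos = pos[order]
        sorted_haps = carrier_haps[order]
        cut = int(np.searchsorted(sorted_pos, p))
        lo = max(0, cut - k_each_side)
        hi = min(len(sorted_haps), cut + k_each_side)
        out.update(int(h) for h in sorted_haps[lo:hi])
    return sorted(out)


def longest_flanking_match(
    haplotypes: np.ndarray,
    site_cm: np.ndarray,
    site: int,
    target_hap: int,
    exclude=(),
    window: int = 400,
):
    """Exact longest contiguous match through ``site`` against all others.

    Scans outwards from ``site`` (within ``window`` sites each way) and
    returns ``(best_hap, best_len_cm)`` maximising left + right contiguous
    agreement with the target.  This is the Viterbi longest-shared-segment
    used by the singleton model; it is also the brute-force oracle against
    which PBWT queries are tested.
    """
    H = np.asarray(haplotypes)
    n, M = H.shape
    lo = max(0, site - window)
    hi = min(M, site + 1 + window)
    eq = H[:, lo:hi] == H[target_hap, lo:hi]
    c = site - lo
    # rightward run length starting at the query site
    right = eq[:, c:]
    first_false_r = np.argmin(right, axis=1)
    all_true_r = right.all(axis=1)
    r_ext = np.where(all_true_r, right.shape[1], first_false_r)
    left = eq[:, : c + 1][:, ::-1]
    first_false_l = np.argmin(left, axis=1)
    all_true_l = left.all(axis=1)
    l_ext = np.where(all_true_l, left.shape[1], first_false_l)
    # match covers [site - (l_ext-1), site + (r_ext-1)] when both > 0
    covers = (l_ext > 0) & (r_ext > 0)
    start = site - (l_ext - 1)
    end = site + (r_ext - 1)
    lengths = np.where(covers, site_cm[np.clip(end, 0, M - 1)] - site_cm[np.clip(start, 0, M - 1)], -1.0)
    mask = np.ones(n, bool)
    mask[list(exclude)] = False
    mask[target_hap] = False
    if not mask.any():
        raise ValueError("need at least one other haplotype")
    lengths = np.where(mask, lengths, -np.inf)
    best = int(np.argmax(lengths))
    return best, float(lengths[best])
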