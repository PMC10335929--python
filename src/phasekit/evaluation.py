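"""Phasing and imputation accuracy metrics.

Truth haplotypes for an offspring are derived from parental genotypes by
inheritance logic (deducible only where transmission is unique), and the
switch error rate (SER) is the fraction of successive deducible heterozygote
pairs whose relative phase disagrees with the truth, stratified by the MAC
bin of the *current* heterozygote (the previous one may belong to any bin).
The SER is invariant to a global haplotype swap of any sample.

Imputation-style concordance follows the standard definitions: aggregate r²
(squared Pearson between pooled imputed dosages and true genotypes per
allele-count bin) and non-reference discordance

    NRD = (e_rr + e_ra + e_aa) / (e_rr + e_ra + e_aa + m_ra + m_aa)

which excludes the (dominant) homozygous-reference matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variants import DEFAULT_MAF_THRESHOLD

UNDEDUCIBLE = -1
MENDEL_ERROR = -2

#: default MAC bins: (lo, hi) inclusive; the last bin collects everything
#: above, i.e. common variants.
DEFAULT_MAC_BINS: Tuple[Tuple[int, Optional[int]], ...] = (
    (1, 1), (2, 5), (6, 10), (11, 20), (21, 50), (51, 100), (101, 500), (501, None),
)


def _bin_label(lo, hi):
    if lo == hi:
        return str(lo)
    if hi is None:
        return f"{lo}+"
    return f"{lo}-{hi}"


@dataclass
class SERReport:
    table: pd.DataFrame  # one row per MAC bin: n_pairs, n_errors, rate
    overall_errors: int
    overall_pairs: int
    n_skipped_samples: int = 0

    @property
    def overall(self) -> float:
        return self.overall_errors / self.overall_pairs if self.overall_pairs else float("nan")

    def rate(self, label: str) -> float:
        row = self.table.loc[self.table["bin"] == label]
        if row.empty or row["n_pairs"].iloc[0] == 0:
            return float("nan")
        return float(row["rate"].iloc[0])


@dataclass
class ConcordanceCounts:
    e_rr: int = 0
    e_ra: int = 0
    e_aa: int = 0
    m_ra: int = 0
    m_aa: int = 0

    def __post_init__(self):
        if min(self.e_rr, self.e_ra, self.e_aa, self.m_ra, self.m_aa) < 0:
            raise ValueError("counts must be non-negative")


def derive_truth_trio(offspring: np.ndarray, father: np.ndarray, mother: np.ndarray):
    """Per-site offspring phase from trio inheritance logic.

    Returns ``(paternal_allele, flags)``: ``paternal_allele[m]`` is the
    allele on the paternal haplotype at offspring hets where transmission is
    unique, else ``UNDEDUCIBLE``; impossible transmissions are flagged
    ``MENDEL_ERROR`` (and excluded from SER).
    """
    o = np.asarray(offspring)
    f = np.asarray(father)
    m = np.asarray(mother)
    pat = np.full(o.shape, UNDEDUCIBLE, np.int8)
    valid = (o >= 0) & (f >= 0) & (m >= 0)
    het = valid & (o == 1)
    # Mendel check for all offspring genotypes
    f_can = [(f == 0) | (f == 1), (f == 1) | (f == 2)]  # can transmit 0 / 1
    m_can = [(m == 0) | (m == 1), (m == 1) | (m == 2)]
    possible = np.zeros(o.shape, bool)
    for a in (0, 1):
        for b in (0, 1):
            possible |= valid & (o == a + b) & f_can[a] & m_can[b]
    inconsistent = valid & ~possible
    pat[inconsistent] = MENDEL_ERROR
    # deducible het: exactly one of (pat=0,mat=1), (pat=1,mat=0) possible
    p01 = f_can[0] & m_can[1]
    p10 = f_can[1] & m_can[0]
    pat[het & p01 & ~p10 & ~inconsistent] = 0
    pat[het & p10 & ~p01 & ~inconsistent] = 1
    return pat


def derive_truth_duo(offspring: np.ndarray, parent: np.ndarray):
    """Per-site offspring phase from a single genotyped parent.

    Deducible only where the parent is homozygous at an offspring het: the
    parental haplotype then carries the parent's allele.
    """
    o = np.asarray(offspring)
    p = np.asarray(parent)
    out = np.full(o.shape, UNDEDUCIBLE, np.int8)
    valid = (o >= 0) & (p >= 0)
    het = valid & (o == 1)
    out[het & (p == 0)] = 0
    out[het & (p == 2)] = 1
    # parent cannot transmit any allele of the offspring genotype
    out[valid & (o == 2) & (p == 0)] = MENDEL_ERROR
    out[valid & (o == 0) & (p == 2)] = MENDEL_ERROR
    return out


def truth_matrix_from_pedigree(genotypes: np.ndarray, sample_ids: Sequence[str],
                               pedigree: Dict[str, Tuple[Optional[str], Optional[str]]]):
    """Stack per-offspring truth-phase rows (parental allele codes).

    ``pedigree`` maps offspring id to (father, mother); either may be None
    (duo).  Returns ``(offspring_indices, truth_codes)`` with one row per
    offspring present in the genotype matrix.
    """
    idx = {s: i for i, s in enumerate(sample_ids)}
    rows = []
    offs = []
    for child, (father, mother) in pedigree.items():
        if child not in idx:
            continue
        o = genotypes[idx[child]]
        if father in idx and mother in idx:
            rows.append(derive_truth_trio(o, genotypes[idx[father]], genotypes[idx[mother]]))
        elif father in idx or mother in idx:
            parent = idx[father] if father in idx else idx[mother]
            code = derive_truth_duo(o, genotypes[parent])
            if mother in idx and father not in idx:
                # codes are "paternal allele"; for a maternal duo flip them
                flip = code.copy()
                flip[code == 0] = 1
                flip[code == 1] = 0
                code = flip
            rows.append(code)
        else:
            continue
        offs.append(idx[child])
    return np.asarray(offs, np.int64), (np.vstack(rows) if rows else np.empty((0, genotypes.shape[1]), np.int8))


def _orientations_from_truth_codes(est_h0, truth_code):
    """est hap0 allele vs truth paternal allele -> orientation booleans."""
    return est_h0 == truth_code


def truth_codes_from_haplotypes(truth_haplotypes: np.ndarray, genotypes: np.ndarray):
    """Truth-phase codes straight from simulated truth haplotypes.

    The 'paternal' haplotype is truth hap0; every het is deducible.
    """
    N, M = genotypes.shape
    code = np.full((N, M), UNDEDUCIBLE, np.int8)
    het = genotypes == 1
    h0 = truth_haplotypes[0::2]
    code[het] = h0[het]
    return code


def switch_error_rate(est_haplotypes: np.ndarray, truth_codes: np.ndarray,
                      records, mac_bins=DEFAULT_MAC_BINS,
                      sample_indices=None, maf_threshold: float = DEFAULT_MAF_THRESHOLD,
                      include_mask: Optional[np.ndarray] = None) -> SERReport:
    """MAC-stratified switch error rate.

    Parameters
    ----------
    est_haplotypes : (2N, M) phased ALT-coded haplotypes.
    truth_codes : (n_offspring, M) truth-phase codes (allele on the
        paternal/truth-hap0 haplotype at deducible hets, ``UNDEDUCIBLE`` or
        ``MENDEL_ERROR`` elsewhere).
    sample_indices : rows of ``est_haplotypes`` (sample ordinals) matching
        the rows of ``truth_codes``; defaults to 0..n_offspring-1.
    include_mask : optional (n_offspring, M) boolean; hets excluded by the
        mask are dropped from the het sequence before pairing (confidence
        filtering).
    """
    truth_codes = np.atleast_2d(truth_codes)
    n_off, M = truth_codes.shape
    if sample_indices is None:
        sample_indices = np.arange(n_off)
    macs = np.asarray([r.mac for r in records])
    mafs = np.asarray([r.maf for r in records])
    labels = [_bin_label(lo, hi) for lo, hi in mac_bins]
    pairs = {lab: 0 for lab in labels}
    errors = {lab: 0 for lab in labels}

    def bin_of(j):
        mac = macs[j]
        for (lo, hi), lab in zip(mac_bins, labels):
            if hi is None:
                if mac >= lo or mafs[j] >= maf_threshold:
                    return lab
            elif lo <= mac <= hi:
                return lab
        return labels[-1]

    n_skipped = 0
    for row, s in enumerate(sample_indices):
        code = truth_codes[row]
        h0 = est_haplotypes[2 * s]
        h1 = est_haplotypes[2 * s + 1]
        ded = (code >= 0) & (h0 != h1)
        if include_mask is not None:
            ded &= include_mask[row]
        sites = np.nonzero(ded)[0]
        if sites.size < 2:
            n_skipped += 1
            continue
        orient = h0[sites] == code[sites]
        flips = orient[1:] != orient[:-1]
        for j, err in zip(sites[1:], flips):
            lab = bin_of(j)
            pairs[lab] += 1
            errors[lab] += int(err)
    table = pd.DataFrame({
        "bin": labels,
        "n_pairs": [pairs[l] for l in labels],
        "n_errors": [errors[l] for l in labels],
    })
    table["rate"] = np.where(table["n_pairs"] > 0,
                             table["n_errors"] / table["n_pairs"].clip(lower=1), np.nan)
    return SERReport(table=table, overall_errors=int(table["n_errors"].sum()),
                     overall_pairs=int(table["n_pairs"].sum()),
                     n_skipped_samples=n_skipped)


def singleton_inheritance_stats(genotypes: np.ndarray, sample_ids: Sequence[str],
                                pedigree: Dict[str, Tuple[Optional[str], Optional[str]]],
                                singleton_sites: Sequence[int],
                                minor_is_alt: Optional[np.ndarray] = None):
    """Fractions of offspring singletons supported by genotyped parents.

    Trio offspring singletons are *unsupported* when neither parent carries
    the minor allele (a Mendel-inconsistency signature: de novo mutation or
    genotyping error); duo singletons are *supported* when the genotyped
    parent carries it.
    """
    idx = {s: i for i, s in enumerate(sample_ids)}
    g = np.asarray(genotypes)
    if minor_is_alt is None:
        minor_is_alt = np.ones(g.shape[1], bool)
    supported = unsupported = 0
    for child, (father, mother) in pedigree.items():
        if child not in idx:
            continue
        ci = idx[child]
        parents = [idx[p] for p in (father, mother) if p in idx]
        if not parents:
            continue
        for j in singleton_sites:
            gm = g[ci, j] if minor_is_alt[j] else 2 - g[ci, j]
            if gm < 1:
                continue
            pm = [(g[p, j] if minor_is_alt[j] else 2 - g[p, j]) for p in parents]
            if any(x >= 1 for x in pm):
                supported += 1
            else:
                unsupported += 1
    total = supported + unsupported
    return {
        "n_offspring_singletons": total,
        "supported": supported,
        "unsupported": unsupported,
        "fraction_supported": supported / total if total else float("nan"),
        "fraction_unsupported": unsupported / total if total else float("nan"),
    }


def aggregate_r2(dosages: np.ndarray, truth: np.ndarray, allele_counts: np.ndarray,
                 ac_bins: Sequence[int]) -> pd.DataFrame:
    """Squared Pearson correlation per allele-count bin.

    Variants are pooled within each bin (upper edges ``ac_bins``, the first
    bin covering counts up to ``ac_bins[0]``); bins where either pooled
    vector is constant get a missing (NaN) value, not 0.
    """
    dosages = np.asarray(dosages, float)
    truth = np.asarray(truth, float)
    allele_counts = np.asarray(allele_counts)
    edges = list(ac_bins)
    rows = []
    lo = 1
    for hi in edges:
        in_bin = (allele_counts >= lo) & (allele_counts <= hi)
        lab = f"{lo}-{hi}" if hi > lo else str(lo)
        if not in_bin.any():
            rows.append((lab, 0, np.nan))
            lo = hi + 1
            continue
        d = dosages[:, in_bin].ravel()
        t = truth[:, in_bin].ravel()
        ok = (t >= 0) & np.isfinite(d)
        d, t = d[ok], t[ok]
        if d.size < 2 or np.std(d) == 0 or np.std(t) == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(d, t)[0, 1] ** 2)
        rows.append((lab, int(in_bin.sum()), r2))
        lo = hi + 1
    return pd.DataFrame(rows, columns=["bin", "n_variants", "r2"])


def concordance_counts(truth: np.ndarray, called: np.ndarray) -> ConcordanceCounts:
    """Tally match/mismatch counts by true genotype class."""
    t = np.asarray(truth)
    c = np.asarray(called)
    ok = (t >= 0) & (c >= 0)
    t, c = t[ok], c[ok]
    match = t == c
    return ConcordanceCounts(
        e_rr=int(((t == 0) & ~match).sum()),
        e_ra=int(((t == 1) & ~match).sum()),
        e_aa=int(((t == 2) & ~match).sum()),
        m_ra=int(((t == 1) & match).sum()),
        m_aa=int(((t == 2) & match).sum()),
    )


def nrd(counts: ConcordanceCounts) -> float:
    """Non-reference discordance rate."""
    num = counts.e_rr + counts.e_ra + counts.e_aa
    den = num + counts.m_ra + counts.m_aa
    if den == 0:
        raise ValueError("NRD undefined: no non-reference genotypes")
    return num / den


KINSHIP_LO = 0.1767
KINSHIP_HI = 0.3553
IBS0_MAX = 0.0012
MIN_AGE_GAP = 15.0


def select_parent_offspring(pairs: pd.DataFrame, trios: bool = False) -> pd.DataFrame:
    """Filter candidate parent-offspring pairs on kinship/IBS0/age.

    ``pairs`` needs columns ``kinship``, ``ibs0``, ``age_parent``,
    ``age_offspring`` and, for trio assembly, ``offspring``, ``parent`` and
    ``parent_sex``.  Retains pairs with kinship strictly between 0.1767 and
    0.3553, IBS0 strictly below 0.0012 and an age gap strictly above 15
    years.  With ``trios=True``, returns one row per offspring with exactly
    two retained parents of different sex.
    """
    keep = (
        (pairs["kinship"] > KINSHIP_LO)
        & (pairs["kinship"] < KINSHIP_HI)
        & (pairs["ibs0"] < IBS0_MAX)
        & ((pairs["age_parent"] - pairs["age_offspring"]).abs() > MIN_AGE_GAP)
    )
    retained = pairs.loc[keep].copy()
    if not trios:
        return retained
    rows = []
    for child, grp in retained.groupby("offspring"):
        if len(grp) != 2:
            continue
        sexes = set(grp["parent_sex"])
        if len(sexes) != 2:
            continue  # trios require two parents of different sex
        rows.append({
            "offspring": child,
            "father": grp.loc[grp["parent_sex"] == "M", "parent"].iloc[0],
            "mother": grp.loc[grp["parent_sex"] == "F", "parent"].iloc[0],
        })
    return pd.DataFrame(rows, columns=["offspring", "father", "mother"])
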