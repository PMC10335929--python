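"""VCF reading/writing, multiallelic decomposition and site QC.

Reading goes through cyvcf2 (plain or bgzipped VCF; region queries use the
tabix index when available, otherwise stream-filter with 1-based inclusive
semantics).  Multiallelic records are decomposed into one biallelic record
per ALT, recoding other ALT alleles as reference-class — the same
``norm -m-``-style semantics as the standard normalization tools.

Site QC mirrors common sequencing-panel filters: Hardy–Weinberg exact
mid-p, missingness, heterozygote excess (observed/expected het ratio),
an AAscore floor (only when the INFO field exists) and FILTER=PASS.
Drops are attributed to the first failing filter, in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .variants import VariantRecord, compute_mac_maf

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class SiteQCThresholds:
    hwe_p_min: float = 1e-30
    max_missing_fraction: float = 0.10
    het_excess_bounds: Tuple[float, float] = (0.5, 1.5)
    require_filter_pass: bool = False
    aa_score_min: float = 0.5

    def __post_init__(self):
        lo, hi = self.het_excess_bounds
        if lo > hi:
            raise ValueError("het_excess_bounds must be ordered")
        if not (0 <= self.max_missing_fraction <= 1):
            raise ValueError("max_missing_fraction must be in [0, 1]")


@dataclass
class VcfData:
    """In-memory cohort: ALT-dosage genotypes plus phased haplotypes."""

    genotypes: np.ndarray  # (N, M) int8, MISSING for no-call
    haplotypes: np.ndarray  # (2N, M) int8, MISSING where unphased het/missing
    phased: np.ndarray  # (N, M) bool
    records: List[VariantRecord]
    samples: List[str]
    filters: List[str] = field(default_factory=list)
    pp: Optional[np.ndarray] = None  # (N, M) float, NaN where absent


def _region_parse(region: str):
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    beg, end = span.split("-")
    return chrom, int(beg), int(end)


def read_vcf(path, region: Optional[str] = None) -> VcfData:
    """Read a (possibly multiallelic) VCF into matrices.

    Positions stay 1-based; missing genotypes are encoded ``MISSING`` and
    excluded from MAC/MAF; per-haplotype alleles and phased flags are
    preserved.  Multiallelic records are split (see
    :func:`split_multiallelics`); region queries are 1-based inclusive.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    it = vcf
    stream_filter = None
    if region:
        try:  # indexed query; falls back to streaming for plain VCFs
            it = list(vcf(region))
        except Exception:
            vcf.close()
            vcf = VCF(str(path), gts012=False)
            it = vcf
            stream_filter = _region_parse(region)
    raw = []
    for rec in it:
        if stream_filter is not None:
            chrom, beg, end = stream_filter
            if rec.CHROM != chrom:
                continue
            if beg is not None and not (beg <= rec.POS <= end):
                continue
        g = rec.genotype.array()  # (N, 3): allele0, allele1, phased
        if g.shape[1] != 3:
            raise ValueError(f"non-diploid GT at {rec.CHROM}:{rec.POS}")
        alts = [a for a in rec.ALT if a is not None]
        pp = None
        try:
            pp = rec.format("PP")
        except Exception:
            pp = None
        raw.append((rec.CHROM, rec.POS, rec.REF, alts, g[:, 0].copy(),
                    g[:, 1].copy(), g[:, 2].astype(bool), rec.FILTER,
                    dict(rec.INFO), pp))
    vcf.close()
    return _assemble(raw, samples)


def split_multiallelics(raw_records):
    """Decompose raw parsed records into biallelic ones.

    ``raw_records`` items are
    ``(chrom, pos, ref, alts, a0, a1, phased, filter, info, pp)`` with
    allele indices (-1 missing).  Each ALT yields one record; alleles other
    than that ALT are recoded as reference-class; symbolic ALTs are dropped
    with a warning.  GT ``1/2`` therefore becomes het in both derived
    records.
    """
    out = []
    for chrom, pos, ref, alts, a0, a1, phased, filt, info, pp in raw_records:
        for k, alt in enumerate(alts, start=1):
            if alt.startswith("<"):
                logger.warning("dropping symbolic ALT %s at %s:%s", alt, chrom, pos)
                continue
            b0 = np.where(a0 < 0, MISSING, (a0 == k).astype(np.int8))
            b1 = np.where(a1 < 0, MISSING, (a1 == k).astype(np.int8))
            out.append((chrom, pos, ref, alt, b0.astype(np.int8),
                        b1.astype(np.int8), phased, filt, info, pp))
    return out


def _assemble(raw, samples) -> VcfData:
    bi = split_multiallelics(raw)
    N = len(samples)
    M = len(bi)
    genotypes = np.full((N, M), MISSING, np.int8)
    haplotypes = np.full((2 * N, M), MISSING, np.int8)
    phased = np.zeros((N, M), bool)
    records: List[VariantRecord] = []
    filters: List[str] = []
    pp_mat = None
    for j, (chrom, pos, ref, alt, b0, b1, ph, filt, info, pp) in enumerate(bi):
        miss = (b0 == MISSING) | (b1 == MISSING)
        genotypes[:, j] = np.where(miss, MISSING, b0 + b1)
        haplotypes[0::2, j] = b0
        haplotypes[1::2, j] = b1
        ph = ph & ~miss
        het = ~miss & ((b0 + b1) == 1)
        unphased_het = het & ~ph
        haplotypes[0::2, j][unphased_het] = MISSING
        haplotypes[1::2, j][unphased_het] = MISSING
        phased[:, j] = ph | (~miss & ~het)  # homozygotes are trivially phased
        records.append(VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                                     info=dict(info)))
        filters.append(filt if filt is not None else "PASS")
        if pp is not None:
            if pp_mat is None:
                pp_mat = np.full((N, M), np.nan)
            pp_mat[:, j] = np.asarray(pp, float).reshape(-1)
    mac, maf, minor_is_alt, n_called = compute_mac_maf(genotypes)
    for j, r in enumerate(records):
        r.mac = int(mac[j])
        r.maf = float(maf[j])
        r.minor_is_alt = bool(minor_is_alt[j])
        r.n_called = int(n_called[j])
    return VcfData(genotypes=genotypes, haplotypes=haplotypes, phased=phased,
                   records=records, samples=samples, filters=filters, pp=pp_mat)


def write_vcf(path, records: Sequence[VariantRecord], samples: Sequence[str],
              genotypes: Optional[np.ndarray] = None,
              haplotypes: Optional[np.ndarray] = None,
              pp: Optional[np.ndarray] = None,
              contig: Optional[str] = None):
    """Write a VCF 4.2 text file.

    Pass ``haplotypes`` for phased output (``|`` separators) or
    ``genotypes`` for unphased (``/``).  ``pp`` adds a per-genotype PP
    FORMAT field (Float, written where finite).  AC/AN INFO fields are
    emitted for every site, monomorphic ones included.
    """
    if (genotypes is None) == (haplotypes is None):
        raise ValueError("pass exactly one of genotypes/haplotypes")
    N = len(samples)
    M = len(records)
    if contig is None:
        contig = records[0].chrom if records else "1"
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig}>",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if pp is not None:
        lines.append('##FORMAT=<ID=PP,Number=1,Type=Float,Description="Phasing confidence">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    if haplotypes is not None:
        h = np.asarray(haplotypes)
        a0, a1, sep = h[0::2], h[1::2], "|"
    else:
        g = np.asarray(genotypes)
        a0 = np.where(g == 2, 1, np.where(g == MISSING, MISSING, 0))
        a1 = np.where(g >= 1, 1, np.where(g == MISSING, MISSING, 0))
        sep = "/"
    allele_str = np.array([".", "0", "1"])
    for j, r in enumerate(records):
        s0 = allele_str[a0[:, j] + 1]
        s1 = allele_str[a1[:, j] + 1]
        gt = np.char.add(np.char.add(s0, sep), s1)
        fmt = "GT"
        if pp is not None:
            conf = pp[:, j]
            has = np.isfinite(conf)
            if has.any():
                fmt = "GT:PP"
                tail = np.where(has, np.char.mod("%.4f", np.nan_to_num(conf)), ".")
                gt = np.char.add(np.char.add(gt, ":"), tail)
        called = a0[:, j] >= 0
        ac = int((a0[:, j][called] + a1[:, j][called]).clip(0).sum()) if haplotypes is not None \
            else int(np.asarray(genotypes)[:, j][np.asarray(genotypes)[:, j] >= 0].sum())
        an = 2 * int(called.sum())
        lines.append("\t".join([
            r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS",
            f"AC={ac};AN={an}", fmt, "\t".join(gt.tolist()),
        ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def hwe_midp(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Hardy–Weinberg exact test (Wigginton et al.), mid-p variant.

    Enumerates the conditional distribution of heterozygote counts given
    the minor-allele count and sums probabilities of configurations no more
    likely than the observed one, counting the observed configuration with
    weight 1/2 (mid-p).
    """
    if n_hom_minor > n_hom_major:
        n_hom_minor, n_hom_major = n_hom_major, n_hom_minor
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * n_hom_minor + n_het  # minor allele count, <= n
    if rare == 0:
        return 1.0  # monomorphic: a single configuration, no evidence
    obs_het = n_het
    # heterozygote count shares the parity of the minor allele count
    mid = int(round(rare * (2.0 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        h -= 2
    h = mid
    while h <= rare - 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs.get(obs_het, 0.0) / total
    p = 0.0
    for h, q in probs.items():
        q /= total
        if h == obs_het:
            p += 0.5 * q  # mid-p
        elif q <= p_obs:
            p += q
    return min(p, 1.0)


def apply_site_qc(genotypes: np.ndarray, records: Sequence[VariantRecord],
                  thresholds: Optional[SiteQCThresholds] = None,
                  filters: Optional[Sequence[str]] = None,
                  gq: Optional[np.ndarray] = None):
    """Per-site QC with first-failing-reason attribution.

    Returns ``(kept_indices, drop_counts)`` where ``drop_counts`` maps
    reason -> count and ``kept + sum(drops) == n_sites``.  Missingness
    counts missing GT or, when ``gq`` is given, GQ == 0.
    """
    thresholds = thresholds or SiteQCThresholds()
    g = np.asarray(genotypes)
    N, M = g.shape
    kept = []
    drops = {"hwe": 0, "missingness": 0, "het_excess": 0, "aascore": 0, "filter": 0}
    lo, hi = thresholds.het_excess_bounds
    for j in range(M):
        col = g[:, j]
        miss = col == MISSING
        if gq is not None:
            miss = miss | (gq[:, j] == 0)
        called = col[~miss]
        n_het = int((called == 1).sum())
        n_aa = int((called == 2).sum())
        n_rr = int((called == 0).sum())
        if hwe_midp(n_het, min(n_aa, n_rr), max(n_aa, n_rr)) < thresholds.hwe_p_min:
            drops["hwe"] += 1
            continue
        if miss.mean() > thresholds.max_missing_fraction:
            drops["missingness"] += 1
            continue
        nc = len(called)
        if nc > 0 and n_het > 0:
            p = (2 * n_aa + n_het) / (2.0 * nc)
            exp_het = 2.0 * p * (1 - p) * nc
            if exp_het > 0:
                ratio = n_het / exp_het
                if ratio < lo or ratio > hi:
                    drops["het_excess"] += 1
                    continue
        aascore = records[j].info.get("AAscore") if records else None
        if aascore is not None and float(aascore) < thresholds.aa_score_min:
            drops["aascore"] += 1
            continue
        if thresholds.require_filter_pass and filters is not None:
            if filters[j] not in ("PASS", None, "."):
                drops["filter"] += 1
                continue
        kept.append(j)
    return np.asarray(kept, np.int64), drops
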