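"""Core variant record types shared across the package.

A :class:`VariantRecord` describes one biallelic site together with its
minor-allele count (MAC) and frequency (MAF) computed on the phasing cohort,
and its frequency class:

``common``
    MAF at or above the common threshold (0.1% by default).
``rare``
    MAF below the threshold but MAC > 1.
``singleton``
    MAC exactly 1 (one minor allele on one haplotype in the whole cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

COMMON = "common"
RARE = "rare"
SINGLETON = "singleton"
#: MAC == 0 sites carry no phase information; they bypass every model.
MONOMORPHIC = "monomorphic"

VARIANT_CLASSES = (COMMON, RARE, SINGLETON, MONOMORPHIC)

#: Default common/rare MAF boundary (0.1%).
DEFAULT_MAF_THRESHOLD = 1e-3


@dataclass
class VariantRecord:
    """One biallelic site.

    ``mac``/``maf`` refer to the *minor* allele over the called genotypes of
    the cohort the record was computed on.  ``minor_is_alt`` records which
    VCF allele is the minor one (ties count ALT as minor).
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    mac: int = 0
    maf: float = 0.0
    n_called: int = 0
    minor_is_alt: bool = True
    vclass: Optional[str] = None
    info: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __repr__(self) -> str:  # compact: records appear in big lists
        return (
            f"VariantRecord({self.chrom}:{self.pos} {self.ref}>{self.alt} "
            f"mac={self.mac} class={self.vclass})"
        )


def compute_mac_maf(genotypes: np.ndarray, missing: int = -1):
    """Per-site MAC/MAF over a diploid genotype matrix.

    Parameters
    ----------
    genotypes:
        ``(n_samples, n_sites)`` integer matrix of ALT-allele dosages
        (0/1/2), with ``missing`` marking no-calls.

    Returns
    -------
    mac, maf, minor_is_alt, n_called : per-site arrays.
    """
    g = np.asarray(genotypes)
    called = g != missing
    n_called = called.sum(axis=0)
    alt_count = np.where(called, g, 0).sum(axis=0)
    an = 2 * n_called
    ref_count = an - alt_count
    minor_is_alt = alt_count <= ref_count
    mac = np.minimum(alt_count, ref_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(an > 0, mac / np.maximum(an, 1), 0.0)
    return mac.astype(np.int64), maf, minor_is_alt, n_called.astype(np.int64)


def records_from_matrix(
    genotypes: np.ndarray,
    positions: np.ndarray,
    chrom: str = "1",
    ref: str = "A",
    alt: str = "C",
) -> list:
    """Build :class:`VariantRecord` objects from a genotype matrix."""
    mac, maf, minor_is_alt, n_called = compute_mac_maf(genotypes)
    return [
        VariantRecord(
            chrom=chrom,
            pos=int(p),
            ref=ref,
            alt=alt,
            mac=int(mac[j]),
            maf=float(maf[j]),
            n_called=int(n_called[j]),
            minor_is_alt=bool(minor_is_alt[j]),
        )
        for j, p in enumerate(positions)
    ]
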