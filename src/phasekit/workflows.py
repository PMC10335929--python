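"""End-to-end pipeline runners and simulation experiments.

``phase_cohort`` chains the full stack — classify, scaffold phasing, sparse
rare store, rare/singleton phasing — on an in-memory cohort; the experiment
functions wrap it on simulated panels and score the results against the
simulation truth.  These runners are what the command-line interface, the
test-suite end-to-end checks and the acceptance script all share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .evaluation import (SERReport, switch_error_rate, truth_codes_from_haplotypes)
from .rare import (PhaseCall, assemble_phased_matrix, build_sparse_store,
                   phase_all_rare)
from .scaffold import HaplotypeScaffold, LSParams, classify_variants, phase_common
from .simdata import SimConfig, cohort_view, simulate_panel, simulate_trios

#: study conditions for simulated cohorts (see docs/methods.md)
SIM_REGION_CM = 5.0

#: Li–Stephens settings matched to the simulated demography: coalescence to
#: a small founder pool within ~30 generations corresponds to a tiny
#: effective population size, and the mutation-free copying within the
#: simulation tolerates a larger copying error (see docs/methods.md).
SIM_LS_KW = dict(n_eff=100.0, theta=3e-4, k_states=16)


def cohort_config(n_samples: int, n_sites: int, seed: int, **overrides) -> SimConfig:
    base = dict(
        n_founders=max(40, n_samples // 10),
        n_samples=n_samples,
        n_sites=n_sites,
        region_length_cm=SIM_REGION_CM,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class PhasedCohort:
    scaffold: HaplotypeScaffold
    calls: List[PhaseCall]
    phased: np.ndarray  # (2N, M) ALT-coded
    records: list
    common_idx: np.ndarray
    het_posterior: np.ndarray  # (N, M_common)
    pp: Dict[Tuple[int, int], float] = field(default_factory=dict)
    store: object = None

    def pp_matrix(self, n_samples: int, n_sites: int) -> np.ndarray:
        out = np.full((n_samples, n_sites), np.nan)
        for (s, j), c in self.pp.items():
            out[s, j] = c
        return out


def phase_cohort(genotypes, records, site_cm=None, positions=None,
                 params: Optional[LSParams] = None, seed: int = 0,
                 sample_ids=None) -> PhasedCohort:
    """Run the full two-stage phasing pipeline on one cohort."""
    params = params or LSParams(seed=seed)
    g = np.asarray(genotypes, dtype=np.int8)
    if positions is None:
        positions = np.asarray([r.pos for r in records])
    classify_variants(records)
    scaffold, het_post, common_idx = phase_common(g, records, site_cm, params, sample_ids)
    store = build_sparse_store(g, records,
                               common_positions=np.asarray(positions)[common_idx],
                               positions=positions)
    calls, rare_h = phase_all_rare(scaffold, store, params, seed=seed + 1)
    phased = assemble_phased_matrix(scaffold, store, rare_h, records, common_idx)
    pp = {(c.sample, c.variant): c.confidence for c in calls}
    return PhasedCohort(scaffold=scaffold, calls=calls, phased=phased,
                        records=records, common_idx=common_idx,
                        het_posterior=het_post, pp=pp, store=store)


def call_correctness(result: PhasedCohort, truth_haplotypes: np.ndarray,
                     window: int = 25) -> np.ndarray:
    """Per-call correctness against simulation truth.

    The estimated haplotype labels of a sample are aligned to the truth
    labels locally — by majority agreement over the nearest ``window``
    common heterozygous sites around the rare variant — so distal switch
    errors in the scaffold do not contaminate the score of a local call.
    """
    est = result.scaffold.haplotypes
    common_idx = result.common_idx
    truth_c = truth_haplotypes[:, common_idx]
    out = np.zeros(len(result.calls), bool)
    # per-sample cache of common het positions
    het_cache: Dict[int, np.ndarray] = {}
    pos_common = np.asarray([r.pos for r in result.scaffold.records])
    positions = np.asarray([r.pos for r in result.records])
    for i, call in enumerate(result.calls):
        s = call.sample
        hets = het_cache.get(s)
        if hets is None:
            hets = np.nonzero(est[2 * s] != est[2 * s + 1])[0]
            het_cache[s] = hets
        r = result.records[call.variant]
        t0 = truth_haplotypes[2 * s, call.variant]
        minor_val = 1 if r.minor_is_alt else 0
        truth_orient = 0 if t0 == minor_val else 1
        if hets.size == 0:
            out[i] = call.orientation == truth_orient
            continue
        center = np.searchsorted(pos_common[hets], positions[call.variant])
        lo = max(0, center - window // 2)
        sel = hets[lo:lo + window]
        agree = float(np.mean(est[2 * s, sel] == truth_c[2 * s, sel]))
        aligned = agree >= 0.5
        out[i] = (call.orientation == truth_orient) if aligned \
            else (call.orientation == 1 - truth_orient)
    return out


@dataclass
class ExperimentResult:
    n_samples: int
    seed: int
    calls: List[PhaseCall]
    correct: np.ndarray  # per call
    random_correct: np.ndarray  # per call, coin-flip baseline
    macs: np.ndarray  # per call
    is_singleton: np.ndarray
    confidences: np.ndarray
    ser: SERReport
    scaffold_ser: SERReport

    def error_rate(self, mask) -> float:
        mask = np.asarray(mask, bool)
        if not mask.any():
            return float("nan")
        return float(1.0 - self.correct[mask].mean())

    def random_error_rate(self, mask) -> float:
        mask = np.asarray(mask, bool)
        if not mask.any():
            return float("nan")
        return float(1.0 - self.random_correct[mask].mean())

    @property
    def rare_mask(self) -> np.ndarray:
        return ~self.is_singleton

    def mac_mask(self, lo: int, hi: int) -> np.ndarray:
        return (self.macs >= lo) & (self.macs <= hi) & ~self.is_singleton


def run_phasing_experiment(n_samples: int, n_sites: int, seed: int,
                           params: Optional[LSParams] = None) -> ExperimentResult:
    """Simulate a cohort, phase it, and score every rare/singleton call."""
    config = cohort_config(n_samples, n_sites, seed)
    truth, genotypes, records = simulate_panel(config)
    params = params or LSParams(seed=seed, **SIM_LS_KW)
    result = phase_cohort(genotypes, records, site_cm=truth.site_cm,
                          positions=truth.positions_bp, params=params, seed=seed,
                          sample_ids=truth.sample_ids)
    correct = call_correctness(result, truth.true_haplotypes)
    rng = np.random.default_rng(seed + 77)
    random_orient = rng.integers(0, 2, size=len(result.calls))
    random_correct = np.empty(len(result.calls), bool)
    macs = np.empty(len(result.calls), np.int64)
    is_single = np.empty(len(result.calls), bool)
    confs = np.empty(len(result.calls))
    for i, call in enumerate(result.calls):
        r = result.records[call.variant]
        macs[i] = r.mac
        is_single[i] = call.is_singleton
        confs[i] = call.confidence
        # a random orientation is correct iff it matches the truth; relative
        # to our call: correct_random = correct_ours XOR (orientations differ)
        random_correct[i] = correct[i] ^ (random_orient[i] != call.orientation)
    codes = truth_codes_from_haplotypes(truth.true_haplotypes, genotypes)
    ser = switch_error_rate(result.phased, codes, records)
    scaffold_codes = codes[:, result.common_idx]
    scaffold_ser = switch_error_rate(result.scaffold.haplotypes, scaffold_codes,
                                     result.scaffold.records)
    return ExperimentResult(n_samples=n_samples, seed=seed, calls=result.calls,
                            correct=correct, random_correct=random_correct,
                            macs=macs, is_singleton=is_single, confidences=confs,
                            ser=ser, scaffold_ser=scaffold_ser)


def singleton_random_baseline(seed: int, n_panel: int = 1000, n_trios: int = 400,
                              n_sites: int = 6000):
    """Random-orientation singleton phasing on trio offspring.

    Builds a trio cohort, keeps offspring plus unrelated samples (parents
    excluded, as when accuracy is measured on offspring), finds cohort
    singletons carried by offspring, and assigns each minor allele to a
    uniformly random haplotype.  Returns ``(n_correct, n_total)`` against
    the inheritance truth.
    """
    config = cohort_config(n_panel, n_sites, seed,
                           singleton_fraction=0.12)
    truth, _, _ = simulate_panel(config)
    truth = simulate_trios(truth, n_trios, seed=seed + 1)
    idx, H, G = cohort_view(truth, exclude_parents=True)
    offspring_rows = {i for i, s in enumerate(idx) if truth.sample_ids[s].endswith("_child")}
    alt_count = H.sum(axis=0)
    n_hap = H.shape[0]
    rng = np.random.default_rng(seed + 2)
    n_total = n_correct = 0
    for j in np.nonzero((alt_count == 1) | (alt_count == n_hap - 1))[0]:
        minor = 1 if alt_count[j] == 1 else 0
        carrier_hap = int(np.nonzero(H[:, j] == minor)[0][0])
        if carrier_hap // 2 not in offspring_rows:
            continue
        n_total += 1
        n_correct += int(rng.integers(2) == carrier_hap % 2)
    return n_correct, n_total


def comphet_calibration(n_individuals: int = 5000, n_genes: int = 120,
                        n_var_per_gene: int = 25, carrier_p: float = 0.02,
                        seed: int = 0):
    """Observed vs expected compound-het events under independent phase.

    Variants are placed as heterozygotes independently per individual and
    assigned to a haplotype with a fair coin (truth-phased data with
    independent placement).  Returns the pooled observed/expected ratio and
    the same ratio after randomizing phase.
    """
    from .comphet import AnnotatedVariant, find_comphet, randomize_phase
    from .variants import VariantRecord

    rng = np.random.default_rng(seed)
    M = n_genes * n_var_per_gene
    het = rng.random((n_individuals, M)) < carrier_p
    side = rng.integers(0, 2, size=(n_individuals, M))
    H = np.zeros((2 * n_individuals, M), np.uint8)
    H[0::2][het & (side == 0)] = 1
    H[1::2][het & (side == 1)] = 1
    records = []
    annotations = []
    for j in range(M):
        gene = f"G{j // n_var_per_gene}"
        r = VariantRecord(chrom="1", pos=j + 1, ref="A", alt="C",
                          mac=int(het[:, j].sum()), maf=float(het[:, j].mean() / 2),
                          vclass="rare")
        records.append(r)
        annotations.append(AnnotatedVariant(chrom="1", pos=j + 1, ref="A", alt="C",
                                            gene=gene, effect="LoF"))
    samples = [f"I{i}" for i in range(n_individuals)]
    _, table = find_comphet(H, records, samples, annotations, "LoF")
    obs = float(table["n_events"].sum())
    exp = float(table["expected_events"].sum())
    Hr = randomize_phase(H, seed=seed + 1)
    _, table_r = find_comphet(Hr, records, samples, annotations, "LoF")
    obs_r = float(table_r["n_events"].sum())
    return {
        "observed": obs,
        "expected": exp,
        "ratio": obs / exp if exp else float("nan"),
        "randomized_observed": obs_r,
        "randomized_ratio": obs_r / exp if exp else float("nan"),
        "n_ind_gene_pairs": int(table["n_ind_2plus"].sum()),
    }
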