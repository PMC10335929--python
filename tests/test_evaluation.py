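import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasekit.evaluation import (MENDEL_ERROR, UNDEDUCIBLE, ConcordanceCounts,
                                 aggregate_r2, concordance_counts,
                                 derive_truth_duo, derive_truth_trio, nrd,
                                 select_parent_offspring,
                                 singleton_inheritance_stats,
                                 switch_error_rate,
                                 truth_codes_from_haplotypes)
from phasekit.variants import VariantRecord


def rec(mac, pos, maf=None):
    return VariantRecord(chrom="1", pos=pos, ref="A", alt="C", mac=mac,
                         maf=maf if maf is not None else mac / 1000)


class TestTruthDerivation:
    @pytest.mark.parametrize("o,f,m,expected", [
        (1, 0, 2, 0),            # father hom-ref -> paternal allele is ref
        (1, 2, 0, 1),
        (1, 1, 1, UNDEDUCIBLE),  # both parents het
        (1, 0, 0, MENDEL_ERROR),  # impossible transmission
        (1, 2, 2, MENDEL_ERROR),
        (0, 2, 0, MENDEL_ERROR),  # hom-ref child of hom-alt father
        (2, 1, 1, UNDEDUCIBLE),   # hom sites carry no phase information
        (1, 0, 1, 0),             # father can only give ref
        (1, 1, 2, 0),             # mother must give alt
    ])
    def test_trio_logic(self, o, f, m, expected):
        out = derive_truth_trio(np.array([o]), np.array([f]), np.array([m]))
        if expected in (UNDEDUCIBLE, MENDEL_ERROR):
            assert out[0] == expected
        else:
            assert out[0] == expected

    @pytest.mark.parametrize("o,p,expected", [
        (1, 2, 1),               # parent hom-alt -> parental hap carries alt
        (1, 0, 0),
        (1, 1, UNDEDUCIBLE),
        (2, 0, MENDEL_ERROR),
        (0, 2, MENDEL_ERROR),
    ])
    def test_duo_logic(self, o, p, expected):
        out = derive_truth_duo(np.array([o]), np.array([p]))
        assert out[0] == expected

    def test_missing_excluded(self):
        out = derive_truth_trio(np.array([1]), np.array([-1]), np.array([0]))
        assert out[0] == UNDEDUCIBLE


class TestSwitchErrorRate:
    def _simple(self, orient_flags):
        """Build a one-sample cohort whose per-het orientation-vs-truth
        sequence is exactly ``orient_flags``."""
        m = len(orient_flags)
        truth_h0 = np.zeros(m, np.int8)  # truth: hap0 carries ref at hets
        est = np.zeros((2, m), np.uint8)
        for j, ok in enumerate(orient_flags):
            est[0, j] = 0 if ok else 1
            est[1, j] = 1 - est[0, j]
        codes = truth_h0[None, :]
        records = [rec(10, j + 1) for j in range(m)]
        return est, codes, records

    def test_perfect_phasing_zero_ser(self):
        est, codes, records = self._simple([True] * 6)
        rep = switch_error_rate(est, codes, records)
        assert rep.overall == 0.0

    def test_hand_enumerated_sequence(self):
        """[match, flip, flip, match] -> errors at hets 2 and 4: 2/3."""
        est, codes, records = self._simple([True, False, False, True])
        rep = switch_error_rate(est, codes, records)
        assert rep.overall_pairs == 3
        assert rep.overall_errors == 2
        assert rep.overall == pytest.approx(2 / 3)

    def test_global_swap_invariance(self):
        est, codes, records = self._simple([True, False, True, False, True])
        rep1 = switch_error_rate(est, codes, records)
        swapped = est[::-1].copy()  # swap hap0/hap1
        rep2 = switch_error_rate(swapped, codes, records)
        assert rep1.overall == rep2.overall
        # all flips = fully swapped sample: SER 0
        est3, codes3, records3 = self._simple([False] * 5)
        assert switch_error_rate(est3, codes3, records3).overall == 0.0

    def test_error_attributed_to_current_het_bin(self):
        est, codes, records = self._simple([True, False, True])
        records[1] = rec(2, 2)   # the first error lands at this MAC-2 het
        records[2] = rec(30, 3)  # the second at this MAC-30 het
        rep = switch_error_rate(est, codes, records)
        assert rep.rate("2-5") == 1.0
        assert rep.rate("21-50") == 1.0

    def test_single_het_sample_skipped(self):
        est, codes, records = self._simple([True])
        rep = switch_error_rate(est, codes, records)
        assert rep.overall_pairs == 0 and rep.n_skipped_samples == 1

    def test_random_orientation_near_half(self):
        rng = np.random.default_rng(0)
        m, n = 400, 20
        truth = rng.integers(0, 2, (2 * n, m)).astype(np.uint8)
        g = truth[0::2] + truth[1::2]
        codes = truth_codes_from_haplotypes(truth, g)
        est = truth.copy()
        het = g == 1
        flip = rng.random((n, m)) < 0.5
        f = het & flip
        e0 = est[0::2]
        e1 = est[1::2]
        t = e0[f]
        e0[f] = e1[f]
        e1[f] = t
        records = [rec(100, j + 1, maf=0.3) for j in range(m)]
        rep = switch_error_rate(est, codes, records)
        assert rep.overall == pytest.approx(0.5, abs=0.02)

    def test_include_mask_filters_hets(self):
        est, codes, records = self._simple([True, False, True, True])
        mask = np.array([[True, False, True, True]])
        rep = switch_error_rate(est, codes, records, include_mask=mask)
        # the flipped het is removed: remaining sequence has no switches
        assert rep.overall_errors == 0 and rep.overall_pairs == 2


class TestSingletonInheritance:
    def test_zero_de_novo_trios_all_supported(self):
        g = np.array([
            [1, 1],   # child carries both singletons
            [1, 0],   # father carries the first
            [0, 1],   # mother carries the second
        ], np.int8)
        stats = singleton_inheritance_stats(
            g, ["c", "f", "m"], {"c": ("f", "m")}, [0, 1])
        assert stats["fraction_unsupported"] == 0.0
        assert stats["n_offspring_singletons"] == 2

    def test_de_novo_unsupported(self):
        g = np.array([[1], [0], [0]], np.int8)
        stats = singleton_inheritance_stats(
            g, ["c", "f", "m"], {"c": ("f", "m")}, [0])
        assert stats["fraction_unsupported"] == 1.0

    def test_duo_transmission_coin_flip(self):
        """Duo offspring singletons at zero de-novo rate: the genotyped
        parent carries the allele ~50% of the time (the other half came
        from the ungenotyped parent)."""
        rng = np.random.default_rng(1)
        n = 2000
        child = np.ones((1, n), np.int8)
        parent = (rng.random(n) < 0.5).astype(np.int8)[None, :]
        other = 1 - parent
        g = np.vstack([child, parent])
        stats = singleton_inheritance_stats(
            g, ["c", "p"], {"c": ("p", None)}, list(range(n)))
        assert stats["fraction_supported"] == pytest.approx(0.5, abs=0.04)


class TestConcordance:
    def test_nrd_worked_example(self):
        assert nrd(ConcordanceCounts(1, 2, 1, 10, 6)) == pytest.approx(0.2)

    def test_nrd_limits(self):
        assert nrd(ConcordanceCounts(0, 0, 0, 5, 5)) == 0.0
        assert nrd(ConcordanceCounts(1, 1, 1, 0, 0)) == 1.0
        with pytest.raises(ValueError):
            nrd(ConcordanceCounts(0, 0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConcordanceCounts(-1, 0, 0, 0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=1, max_size=60))
    def test_counts_and_nrd_match_direct_formula(self, pairs):
        truth = np.array([a for a, _ in pairs])
        called = np.array([b for _, b in pairs])
        c = concordance_counts(truth, called)
        err = sum(1 for a, b in pairs if a != b)
        match_nonref = sum(1 for a, b in pairs if a == b and a > 0)
        assert c.e_rr + c.e_ra + c.e_aa == err
        assert c.m_ra + c.m_aa == match_nonref
        if err + match_nonref > 0:
            assert nrd(c) == pytest.approx(err / (err + match_nonref))

    def test_aggregate_r2_perfect_and_missing(self):
        truth = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1]], np.int8)
        dos = truth.astype(float)
        ac = np.array([2, 10, 40])
        out = aggregate_r2(dos, truth, ac, [5, 20, 50])
        assert out["r2"].iloc[0] == pytest.approx(1.0)
        # constant dosage in a bin -> missing, not zero
        dos2 = dos.copy()
        dos2[:, 2] = 1.0
        out2 = aggregate_r2(dos2, truth, ac, [5, 20, 50])
        assert np.isnan(out2["r2"].iloc[2])

    def test_aggregate_r2_sign_blind(self):
        truth = np.array([[0, 1, 2, 1, 0]], np.int8).T.repeat(2, axis=1)
        dos = 2.0 - truth
        ac = np.array([3, 3])
        out = aggregate_r2(dos, truth, ac, [5])
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_r2_matches_numpy_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 3, (5, 5)).astype(float)
        dos = np.clip(truth + rng.normal(0, 0.5, (5, 5)), 0, 2)
        ac = rng.integers(1, 100, 5)
        out = aggregate_r2(dos, truth, ac, [100])
        t = truth.ravel()
        d = dos.ravel()
        if np.std(t) and np.std(d):
            expect = np.corrcoef(d, t)[0, 1] ** 2
            assert out["r2"].iloc[0] == pytest.approx(expect)


class TestPedigreeSelection:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["offspring", "parent", "kinship",
                                           "ibs0", "age_parent",
                                           "age_offspring", "parent_sex"])

    def test_threshold_filters(self):
        pairs = self._pairs([
            ("c1", "p1", 0.25, 0.0005, 58, 30, "M"),   # retained
            ("c2", "p2", 0.40, 0.0005, 58, 30, "M"),   # kinship too high
            ("c3", "p3", 0.10, 0.0005, 58, 30, "M"),   # kinship too low
            ("c4", "p4", 0.25, 0.0050, 58, 30, "M"),   # IBS0 too high
            ("c5", "p5", 0.25, 0.0005, 40, 30, "M"),   # age gap too small
        ])
        out = select_parent_offspring(pairs)
        assert list(out["offspring"]) == ["c1"]

    def test_strict_boundaries(self):
        pairs = self._pairs([
            ("c1", "p1", 0.3553, 0.0005, 58, 30, "M"),  # boundary excluded
            ("c2", "p2", 0.1767, 0.0005, 58, 30, "M"),
            ("c3", "p3", 0.25, 0.0012, 58, 30, "M"),
            ("c4", "p4", 0.25, 0.0005, 45, 30, "M"),    # gap exactly 15
        ])
        assert select_parent_offspring(pairs).empty

    def test_trios_require_different_sex_parents(self):
        pairs = self._pairs([
            ("c1", "f1", 0.25, 0.0005, 60, 30, "M"),
            ("c1", "m1", 0.25, 0.0005, 58, 30, "F"),
            ("c2", "f2", 0.25, 0.0005, 60, 30, "M"),
            ("c2", "f3", 0.25, 0.0005, 58, 30, "M"),  # same-sex pair
        ])
        trios = select_parent_offspring(pairs, trios=True)
        assert list(trios["offspring"]) == ["c1"]
        assert trios.iloc[0]["father"] == "f1"
        assert trios.iloc[0]["mother"] == "m1"
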