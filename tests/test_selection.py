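"""Codon alignments, Ka/Ks estimators, the LRT and the exclusion filters."""

import math

import numpy as np
import pytest
from scipy import stats

from genebirth import selection as sel, simulate as sim
from genebirth.io_formats import ValidationError
from genebirth.selection import (
    CodonAlignment,
    KaKsResult,
    SelectionConfig,
    back_translate_alignment,
    filter_pairs,
    lrt_negative_selection,
    ml_pairwise_omega,
    ng86_kaks,
    summarize_selection,
)


class TestBackTranslate:
    def test_gap_maps_to_three_nt_gap(self):
        aln = back_translate_alignment("M-K", "MAK", "ATGAAA", "ATGGCTAAG")
        assert aln.seq_a == "ATG---AAA"
        assert aln.seq_b == "ATGGCTAAG"

    def test_translation_mismatch_names_residue(self):
        # CDS encodes MAKLH but the protein claims proline at residue 5
        with pytest.raises(ValidationError, match="residue 5"):
            back_translate_alignment("MAKLP", "MAKLH",
                                     "ATGGCTAAGCTACAT", "ATGGCTAAGCTACAT")

    def test_identical_sequences_gap_free(self):
        aln = back_translate_alignment("MAK", "MAK", "ATGGCTAAG", "ATGGCTAAG")
        assert "-" not in aln.seq_a + aln.seq_b

    def test_terminal_stop_trimmed(self):
        aln = back_translate_alignment("MK", "MK", "ATGAAATAA", "ATGAAG")
        assert aln.seq_a == "ATGAAA"

    def test_gaps_must_be_codon_blocks(self):
        with pytest.raises(ValidationError, match="3-nt block"):
            CodonAlignment("ATG-A-", "ATGGCT")


class TestNG86:
    def test_identical_sequences(self):
        a, _ = sim.simulate_codon_pair(0.5, 0.0, 2.0, 100, 1)
        r = ng86_kaks(CodonAlignment(a, a))
        assert r.ka == 0.0 and r.ks == 0.0 and not r.saturated

    def test_single_synonymous_change(self):
        a = "ATGGCTAAGCTACAT" * 10
        b = a[:5] + "C" + a[6:]  # GCT -> GCC, both alanine
        r = ng86_kaks(CodonAlignment(a, b))
        assert r.ka == 0.0 and r.ks > 0.0

    def test_single_nonsynonymous_change(self):
        a = "ATGGCTAAGCTACAT" * 10
        b = a[:3] + "TCT" + a[6:]  # Ala -> Ser
        r = ng86_kaks(CodonAlignment(a, b))
        assert r.ks == 0.0 and r.ka > 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_reference_counter(self, seed):
        """Cross-check against the NG86 implementation in Bio.Align.analysis."""
        from Bio.Align import Alignment
        from Bio.Align.analysis import calculate_dn_ds

        a, b = sim.simulate_codon_pair(0.4, 0.25, 2.0, 300, 400 + seed)
        mine = ng86_kaks(CodonAlignment(a, b))
        dn, ds = calculate_dn_ds(Alignment([a, b]), method="NG86")
        assert mine.ka == pytest.approx(dn, abs=1e-9)
        assert mine.ks == pytest.approx(ds, abs=1e-9)

    def test_simulated_pair_ratio_within_band(self):
        """500-codon pairs at omega 0.2, t 0.3: Ka/Ks lands in [0.1, 0.35]."""
        for seed in range(5):
            a, b = sim.simulate_codon_pair(0.2, 0.3, 2.0, 500, 900 + seed)
            r = ng86_kaks(CodonAlignment(a, b))
            assert 0.1 <= r.omega <= 0.35


class TestMLPairwise:
    def test_identical_pair_hits_lower_bound(self):
        a, _ = sim.simulate_codon_pair(0.5, 0.0, 2.0, 200, 3)
        fit = ml_pairwise_omega(CodonAlignment(a, a), kappa=2.0)
        assert fit.t_hat <= 1e-4

    def test_nesting_over_seeds(self):
        for seed in range(8):
            a, b = sim.simulate_codon_pair(0.5, 0.3, 2.0, 300, 1200 + seed)
            aln = CodonAlignment(a, b)
            free = ml_pairwise_omega(aln, kappa=2.0)
            null = ml_pairwise_omega(aln, fix_omega=0.5, kappa=2.0)
            assert free.lnL >= null.lnL - 1e-6

    def test_omega_recovery_at_low_omega(self):
        """20 seeds at omega = 0.1, 500 codons: omega_hat within [0.03, 0.25]."""
        for seed in range(20):
            a, b = sim.simulate_codon_pair(0.1, 0.3, 2.0, 500, 2000 + seed)
            fit = ml_pairwise_omega(CodonAlignment(a, b), kappa=2.0)
            assert 0.03 <= fit.omega_hat <= 0.25, (seed, fit.omega_hat)

    def test_fix_omega_is_respected(self):
        a, b = sim.simulate_codon_pair(0.3, 0.2, 2.0, 200, 11)
        fit = ml_pairwise_omega(CodonAlignment(a, b), fix_omega=0.5, kappa=2.0)
        assert fit.omega_hat == 0.5


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        p, neg = lrt_negative_selection(-100.0, -100.0, omega_hat=0.2)
        assert p == 1.0 and not neg

    def test_chi_square_boundary(self):
        p, _ = lrt_negative_selection(-100.0, -100.0 - 3.841 / 2, omega_hat=0.2)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_significant_high_omega_is_not_negative_selection(self):
        p, neg = lrt_negative_selection(-100.0, -110.0, omega_hat=2.0)
        assert p < 0.05 and not neg

    def test_negative_statistic_beyond_tolerance_raises(self):
        with pytest.raises(ValidationError):
            lrt_negative_selection(-101.0, -100.0, omega_hat=0.2)


def result(ka, ks, neg=False):
    return KaKsResult("a", "b", ka, ks, ka / max(ks, 1e-9), -1.0, -1.0, 0.5, neg)


class TestFilterPairs:
    def test_high_ka_excluded(self):
        out = filter_pairs([result(0.6, 1.0)] + [result(0.1, 0.2)] * 4)
        assert out[0].excluded_reason == sel.REASON_KA

    def test_high_ks_excluded(self):
        out = filter_pairs([result(0.1, 6.0)] + [result(0.1, 0.2)] * 4)
        assert out[0].excluded_reason == sel.REASON_KS

    def test_tukey_fence_hand_computed(self):
        # Ks {0.1, 0.2, 0.2, 0.3, 2.0}: Q1=0.2, Q3=0.3, fence=0.45 -> 2.0 out
        ks_values = [0.1, 0.2, 0.2, 0.3, 2.0]
        out = filter_pairs([result(0.1, k) for k in ks_values])
        reasons = [r.excluded_reason for r in out]
        assert reasons == ["none"] * 4 + [sel.REASON_IQR]

    def test_excluded_pair_loses_negative_call(self):
        out = filter_pairs([result(0.6, 1.0, neg=True)] + [result(0.1, 0.2)] * 4)
        assert not out[0].negative_selection


class TestSummarize:
    @pytest.mark.parametrize("n_neg,n_tot,expect", [
        (19, 94, 20.21), (0, 10, 0.0), (249, 878, 28.36)])
    def test_percentages(self, n_neg, n_tot, expect):
        results = [result(0.1, 0.2, neg=(k < n_neg)) for k in range(n_tot)]
        got = summarize_selection(results)
        assert got == (n_neg, n_tot, expect)

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            summarize_selection([])


class TestSimulatedCalibration:
    """Reduced-size calibration checks; the full-size versions run in the
    acceptance suite."""

    def test_type_one_error_near_nominal(self):
        n_rep, rej = 100, 0
        for k in range(n_rep):
            a, b = sim.simulate_codon_pair(0.5, 0.3, 2.0, 300, 5000 + k)
            aln = CodonAlignment(a, b)
            free = ml_pairwise_omega(aln, kappa=2.0)
            null = ml_pairwise_omega(aln, fix_omega=0.5, kappa=2.0)
            p, _ = lrt_negative_selection(max(free.lnL, null.lnL), null.lnL,
                                          free.omega_hat)
            rej += (p < 0.05)
        # 3 binomial s.e. band at n = 100
        assert abs(rej / n_rep - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_power_at_strong_constraint(self):
        n_rep, rej = 30, 0
        for k in range(n_rep):
            a, b = sim.simulate_codon_pair(0.1, 0.4, 2.0, 500, 7000 + k)
            aln = CodonAlignment(a, b)
            free = ml_pairwise_omega(aln, kappa=2.0)
            null = ml_pairwise_omega(aln, fix_omega=0.5, kappa=2.0)
            _, neg = lrt_negative_selection(max(free.lnL, null.lnL), null.lnL,
                                            free.omega_hat)
            rej += neg
        assert rej / n_rep >= 0.8
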