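import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from symbiorecruit import (
    CodonPairAlignment,
    CodonSimConfig,
    analyze_pair,
    codon_sites,
    count_differences,
    genome_summary,
    jc_correct,
    kaks,
    read_codon_pairs,
    simulate_codon_pair,
    write_codon_pairs,
    z_test,
)
from symbiorecruit.selection import SENSE_CODONS

from _oracles import brute_codon_sites, brute_count_differences


class TestCodonSites:
    @pytest.mark.parametrize(
        "codon, s",
        [("TTT", 1 / 3), ("ATG", 0.0), ("GGG", 1.0), ("TGG", 0.0)],
    )
    def test_worked_examples(self, codon, s):
        got_s, got_n = codon_sites(codon, stop_policy="nonsynonymous")
        assert got_s == pytest.approx(s, abs=1e-12)
        assert got_s + got_n == pytest.approx(3.0, abs=1e-12)

    def test_stop_codon_raises_skip(self):
        from symbiorecruit.selection import SkipCodon

        with pytest.raises(SkipCodon):
            codon_sites("TAA")
        with pytest.raises(SkipCodon):
            codon_sites("ANT")

    def test_site_sum_invariant_under_stop_as_nonsynonymous(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon, stop_policy="nonsynonymous")
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_excluded_policy_never_exceeds_three(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon, stop_policy="excluded")
            assert s + n <= 3.0 + 1e-12


class TestCountDifferences:
    def test_identical_codons(self):
        assert count_differences("AAA", "AAA") == (0.0, 0.0)

    def test_single_change(self):
        assert count_differences("TTT", "TTA") == (0.0, 1.0)  # Phe -> Leu

    def test_pathway_average_two_changes(self):
        sd, nd = count_differences("TTT", "GTA")
        assert (sd, nd) == (0.5, 1.5)


class TestJukesCantor:
    def test_worked_value(self):
        assert jc_correct(0.3) == pytest.approx(-0.75 * math.log(0.6))
        assert jc_correct(0.3) == pytest.approx(0.383119, abs=1e-6)

    def test_zero_and_saturation(self):
        assert jc_correct(0.0) == 0.0
        assert math.isnan(jc_correct(0.75))
        assert math.isnan(jc_correct(0.9))

    @given(st.floats(0.0, 0.74), st.floats(0.0, 0.74))
    def test_monotone(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert jc_correct(lo) <= jc_correct(hi)


class TestEnumerationOracle:
    """codon_sites and count_differences against the independent
    brute-force enumeration over all sense codons and codon pairs."""

    @pytest.mark.parametrize("policy", ["excluded", "nonsynonymous"])
    def test_sites_for_all_sense_codons(self, policy):
        for codon in SENSE_CODONS:
            assert codon_sites(codon, stop_policy=policy) == pytest.approx(
                brute_codon_sites(codon, policy), abs=1e-12
            )

    def test_differences_for_all_codon_pairs(self):
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                assert count_differences(c1, c2) == pytest.approx(
                    brute_count_differences(c1, c2), abs=1e-12
                )


class TestKaKs:
    def test_identical_sequences(self):
        pair = CodonPairAlignment("g", "ATGGCT" * 10, "ATGGCT" * 10)
        result = kaks(pair)
        assert result.Sd == result.Nd == 0.0
        assert result.dS == result.dN == 0.0
        assert math.isnan(result.omega)
        assert "undefined_omega" in result.flags

    def test_gapped_and_ambiguous_codons_skipped(self):
        pair = CodonPairAlignment("g", "ATG---ANTGCT", "ATGAAAGGGGCT")
        result = kaks(pair)
        assert result.n_codons_compared == 2
        assert result.n_codons_skipped == 2

    def test_site_totals_scale_with_codons(self):
        pair = CodonPairAlignment("g", "ATGGCTTTA" * 5, "ATGGCTTTA" * 5)
        result = kaks(pair, stop_policy="nonsynonymous")
        assert result.S + result.N == pytest.approx(3 * result.n_codons_compared)

    def test_matches_biopython_ng86(self):
        """Independent cross-check: Bio.codonalign's NG86 (which counts
        stop-codon mutations as nonsynonymous sites) agrees exactly."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        for seed in range(5):
            pair, _ = simulate_codon_pair(
                CodonSimConfig(n_codons=300, omega=0.3, expected_dS=0.25, seed=100 + seed)
            )
            dn, ds = cal_dn_ds(CodonSeq(pair.seq1), CodonSeq(pair.seq2), method="NG86")
            mine = kaks(pair, stop_policy="nonsynonymous")
            assert mine.dN == pytest.approx(dn, abs=1e-9)
            assert mine.dS == pytest.approx(ds, abs=1e-9)

    def test_omega_recovery(self):
        estimates = [
            kaks(simulate_codon_pair(
                CodonSimConfig(n_codons=2_000, omega=0.2, expected_dS=0.3, seed=s)
            )[0]).omega
            for s in range(30)
        ]
        median = float(np.median(estimates))
        assert 0.2 * 0.7 <= median <= 0.2 * 1.3


class TestZTest:
    def test_identical_sequences_are_degenerate(self):
        pair = CodonPairAlignment("g", "ATGGCT" * 20, "ATGGCT" * 20)
        zt = z_test(pair, B=100, seed=0)
        assert zt.degenerate and zt.p_value == 1.0

    def test_bootstrap_reproducible_under_seed(self):
        pair, _ = simulate_codon_pair(CodonSimConfig(n_codons=300, omega=0.2, expected_dS=0.3, seed=1))
        a = z_test(pair, B=300, seed=42)
        b = z_test(pair, B=300, seed=42)
        assert (a.Z, a.p_value) == (b.Z, b.p_value)

    def test_strong_purifying_signal_detected(self):
        pair, _ = simulate_codon_pair(CodonSimConfig(n_codons=1_000, omega=0.1, expected_dS=0.4, seed=2))
        zt = z_test(pair, B=300, seed=0)
        assert zt.p_value < 0.001

    def test_positive_alternative_flips_the_tail(self):
        pair, _ = simulate_codon_pair(CodonSimConfig(n_codons=1_000, omega=0.1, expected_dS=0.4, seed=3))
        purifying = z_test(pair, B=200, seed=0, alternative="purifying")
        positive = z_test(pair, B=200, seed=0, alternative="positive")
        assert purifying.p_value < 0.05 < positive.p_value

    def test_analytic_and_bootstrap_agree_on_strong_pairs(self):
        agree = 0
        n_pairs = 50
        for seed in range(n_pairs):
            pair, _ = simulate_codon_pair(
                CodonSimConfig(n_codons=500, omega=0.1, expected_dS=0.3, seed=400 + seed)
            )
            boot = z_test(pair, B=200, seed=seed)
            ana = z_test(pair, method="analytic")
            agree += (boot.p_value < 0.05) == (ana.p_value < 0.05)
        assert agree >= 0.9 * n_pairs


class TestGenomeSummary:
    def test_counts_sum_to_n_genes(self):
        results = [
            analyze_pair(
                simulate_codon_pair(CodonSimConfig(n_codons=200, omega=0.3, expected_dS=0.3, seed=s))[0],
                B=100, seed=s,
            )
            for s in range(6)
        ]
        summary = genome_summary(results)
        assert (
            summary.n_purifying_significant
            + summary.n_positive_significant
            + summary.n_not_significant
            == summary.n_genes
            == 6
        )

    def test_strong_purifying_genes_called(self):
        results = []
        for s in range(10):
            pair, _ = simulate_codon_pair(CodonSimConfig(n_codons=1_000, omega=0.1, expected_dS=0.4, seed=s))
            results.append(analyze_pair(pair, B=200, seed=s))
        for s in range(2):
            pair, _ = simulate_codon_pair(CodonSimConfig(n_codons=1_000, omega=1.0, expected_dS=0.4, seed=50 + s))
            results.append(analyze_pair(pair, B=200, seed=50 + s))
        summary = genome_summary(results)
        assert summary.n_purifying_significant >= 9

    def test_degenerate_pairs_not_significant(self):
        results = [
            analyze_pair(CodonPairAlignment("g", "ATGGCT" * 20, "ATGGCT" * 20), B=50, seed=0)
        ]
        summary = genome_summary(results)
        assert summary.n_not_significant == 1


class TestPairedFasta:
    def test_round_trip(self, tmp_path):
        pairs = [
            simulate_codon_pair(CodonSimConfig(n_codons=50, omega=0.5, expected_dS=0.2, seed=s, gene_id=f"g{s}"))[0]
            for s in range(3)
        ]
        path = tmp_path / "pairs.fasta"
        write_codon_pairs(pairs, path)
        back = read_codon_pairs(path)
        assert back == pairs

    def test_missing_member_rejected(self, tmp_path):
        path = tmp_path / "pairs.fasta"
        path.write_text(">g1|1\nATGGCT\n")
        from symbiorecruit import FormatError

        with pytest.raises(FormatError, match="both members"):
            read_codon_pairs(path)
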