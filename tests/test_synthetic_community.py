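import math

import numpy as np
import pytest

from symbiorecruit import (
    CodonSimConfig,
    CommunityConfig,
    ReadSimConfig,
    kaks,
    simulate_codon_pair,
    simulate_genome_pair,
    simulate_reads,
)
from symbiorecruit.io_formats import AnnotationRecord
from symbiorecruit.synthetic_community import (
    SimulationError,
    default_expression_weights,
)


class TestGenomePair:
    def test_zero_divergence_degenerates_to_ancestor(self):
        pair = simulate_genome_pair(CommunityConfig(genome_length=5_000, n_genes=4, divergence=0.0, seed=1, rrna_intervals=(), its_intervals=()))
        assert pair.genomes["A"].residues == pair.genomes["B"].residues == pair.ancestor.residues
        assert pair.realized_divergence == 0.0

    def test_seed_reproducibility(self):
        cfg = CommunityConfig(genome_length=10_000, n_genes=5, seed=99, rrna_intervals=(), its_intervals=())
        a, b = simulate_genome_pair(cfg), simulate_genome_pair(cfg)
        assert a.genomes["A"].residues == b.genomes["A"].residues
        assert a.genomes["B"].residues == b.genomes["B"].residues
        assert np.array_equal(a.variant_positions, b.variant_positions)

    def test_realized_divergence_matches_expectation(self):
        # two lineages each substituted at d/2 with a uniform alternative:
        # P(sites differ) = 2 m (1 - m) + m^2 * 2/3,  m = d/2
        d, L = 0.05, 200_000
        pair = simulate_genome_pair(CommunityConfig(seed=7, divergence=d))
        m = d / 2
        expected = 2 * m * (1 - m) + m**2 * (2 / 3)
        sd = math.sqrt(expected * (1 - expected) / L)
        assert abs(pair.realized_divergence - expected) <= 5 * sd
        # the variant list is exactly the set of differing sites
        ga = np.frombuffer(pair.genomes["A"].residues.encode(), dtype=np.uint8)
        gb = np.frombuffer(pair.genomes["B"].residues.encode(), dtype=np.uint8)
        assert np.array_equal(pair.variant_positions, np.flatnonzero(ga != gb))

    def test_features_do_not_overlap(self, small_pair):
        intervals = sorted((a.start, a.end) for a in small_pair.annotations)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2

    def test_annotations_carry_cluster_labels(self, small_pair):
        labels = {a.cluster_label for a in small_pair.genes}
        assert {"housekeeping", "nif_operon"} <= labels
        gene_ids = {a.gene_id for a in small_pair.genes}
        assert {"recA", "gyrB", "nifH"} <= gene_ids

    def test_impossible_gene_packing_rejected(self):
        with pytest.raises(SimulationError):
            simulate_genome_pair(
                CommunityConfig(genome_length=1_000, n_genes=10, gene_length=500,
                                rrna_intervals=(), its_intervals=(), seed=0)
            )


class TestReadSimulation:
    def test_error_free_reads_are_exact_substrings(self, small_pair):
        rs = simulate_reads(
            small_pair,
            ReadSimConfig(n_reads=200, mode="MG", error_rate=0.0, seed=5),
        )
        for read, truth in zip(rs.reads, rs.truth):
            origin = small_pair.genomes[truth.origin_lineage].residues
            assert read.residues == origin[truth.origin_start : truth.origin_end]
            assert truth.n_errors == 0
            assert truth.true_identity_to_origin == 100.0

    def test_truth_alignment_identity_invariant(self, small_pair):
        rs = simulate_reads(
            small_pair, ReadSimConfig(n_reads=500, mode="MG", error_rate=0.01, seed=6)
        )
        by_read = {}
        for aln in rs.truth_alignments:
            by_read.setdefault(aln.qseqid, {})[aln.genome_id] = aln
        for truth in rs.truth:
            aln = by_read[truth.read_id][truth.origin_lineage]
            assert aln.pident == truth.true_identity_to_origin
            assert aln.mismatch == truth.n_errors
            assert (aln.subject_start, aln.subject_end) == (
                truth.origin_start, truth.origin_end,
            )

    def test_lineage_mixture_is_binomial(self, small_pair):
        n, w = 10_000, 0.9
        rs = simulate_reads(
            small_pair,
            ReadSimConfig(n_reads=n, mode="MG", lineage_weights={"A": w, "B": 1 - w}, seed=8),
        )
        n_a = sum(1 for t in rs.truth if t.origin_lineage == "A")
        sd = math.sqrt(n * w * (1 - w))
        assert abs(n_a - n * w) <= 3 * sd

    def test_mt_reads_contained_in_genes_with_nif_mass(self, small_pair):
        n = 10_000
        rs = simulate_reads(
            small_pair, ReadSimConfig(n_reads=n, mode="MT", seed=9)
        )
        genes = {(g.start, g.end): g for g in small_pair.genes}
        nif = 0
        for truth in rs.truth:
            hosts = [
                g for (s, e), g in genes.items()
                if truth.origin_start >= s and truth.origin_end <= e
            ]
            assert len(hosts) == 1, "MT read not wholly contained in one gene"
            if hosts[0].cluster_label == "nif_operon":
                nif += 1
        sd = math.sqrt(n * 0.25 * 0.75)
        assert abs(nif - 0.25 * n) <= 3 * sd

    def test_mean_coverage_matches_lander_waterman_input(self, small_pair):
        # mean per-position coverage of the origin genome = n * rl * w / L
        n, rl, w = 5_000, 100, 0.8
        L = small_pair.genome_length
        rs = simulate_reads(
            small_pair,
            ReadSimConfig(n_reads=n, mode="MG", lineage_weights={"A": w, "B": 1 - w}, seed=10),
        )
        n_a = sum(1 for t in rs.truth if t.origin_lineage == "A")
        mean_cov = n_a * rl / L
        sd_reads = math.sqrt(n * w * (1 - w))
        assert abs(mean_cov - n * w * rl / L) <= 3 * sd_reads * rl / L

    def test_seed_reproducibility(self, small_pair):
        cfg = ReadSimConfig(n_reads=100, mode="MG", seed=77)
        a = simulate_reads(small_pair, cfg)
        b = simulate_reads(small_pair, cfg)
        assert [r.residues for r in a.reads] == [r.residues for r in b.reads]
        assert a.truth == b.truth

    def test_short_genes_excluded_from_expression_weights(self):
        annotations = [
            AnnotationRecord("g", "gene", 0, 50, "+", "tiny"),
            AnnotationRecord("g", "gene", 100, 1_000, "+", "nifH", "nif_operon"),
            AnnotationRecord("g", "gene", 1_100, 2_000, "+", "recA", "housekeeping"),
        ]
        weights = default_expression_weights(annotations, read_length=100)
        assert "tiny" not in weights
        assert sum(weights.values()) == pytest.approx(1.0)

    def test_mt_mode_without_long_genes_rejected(self):
        pair = simulate_genome_pair(
            CommunityConfig(genome_length=2_000, n_genes=3, gene_length=80,
                            rrna_intervals=(), its_intervals=(), seed=3)
        )
        with pytest.raises(SimulationError):
            simulate_reads(pair, ReadSimConfig(n_reads=10, mode="MT", seed=1))


class TestCodonSimulation:
    def test_zero_distance_keeps_sequences_identical(self):
        pair, truth = simulate_codon_pair(CodonSimConfig(n_codons=50, expected_dS=0.0, seed=2))
        assert pair.seq1 == pair.seq2
        assert truth.syn_events == truth.nonsyn_events == 0

    def test_seed_reproducibility(self):
        cfg = CodonSimConfig(n_codons=100, omega=0.5, expected_dS=0.2, seed=4)
        (a, ta), (b, tb) = simulate_codon_pair(cfg), simulate_codon_pair(cfg)
        assert a.seq1 == b.seq1 and a.seq2 == b.seq2
        assert ta == tb

    def test_no_stop_codons_emitted(self):
        from symbiorecruit.selection import STOP_CODONS

        pair, _ = simulate_codon_pair(CodonSimConfig(n_codons=500, omega=1.0, expected_dS=0.5, seed=11))
        for seq in (pair.seq1, pair.seq2):
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOP_CODONS)

    def test_realized_ds_matches_target(self):
        target = 0.3
        estimates = [
            kaks(simulate_codon_pair(CodonSimConfig(n_codons=2_000, omega=1.0, expected_dS=target, seed=s))[0]).dS
            for s in range(20)
        ]
        assert abs(float(np.median(estimates)) - target) < 0.03

    def test_neutral_omega_estimate_is_unbiased(self):
        # omega = 1, 500 codons: the downstream NG86 estimate over 200
        # replicates should have a median close to 1
        estimates = [
            kaks(simulate_codon_pair(CodonSimConfig(n_codons=500, omega=1.0, expected_dS=0.3, seed=1_000 + s))[0]).omega
            for s in range(200)
        ]
        assert 0.85 <= float(np.median(estimates)) <= 1.15
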