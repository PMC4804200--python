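import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from symbiorecruit import (
    FilterConfig,
    ReadSimConfig,
    align_reads_naive,
    apply_filters,
    best_hit_per_genome,
    competitive_assign,
    genome_recovery,
    identity_histogram,
    recruit,
    simulate_reads,
)
from symbiorecruit.recruitment import AssignedRead

from conftest import make_alignment


def assigned(records):
    return competitive_assign(records)


class TestBestHit:
    def test_highest_bitscore_wins(self):
        lo = make_alignment("r1", bitscore=150.0, sstart=100)
        hi = make_alignment("r1", bitscore=180.0, sstart=200)
        assert best_hit_per_genome([lo, hi]) == [hi]

    def test_single_record_unchanged(self):
        rec = make_alignment("r1")
        assert best_hit_per_genome([rec]) == [rec]

    def test_bitscore_tie_broken_by_pident_then_position(self):
        a = make_alignment("r1", pident=98.0, sstart=100)
        b = make_alignment("r1", pident=99.0, sstart=200)
        assert best_hit_per_genome([a, b]) == [b]
        c = make_alignment("r1", pident=99.0, sstart=300)
        assert best_hit_per_genome([b, c]) == [b]  # smallest (sstart, send)


class TestApplyFilters:
    def test_toy_table(self, toy_filter_inputs):
        records, read_lengths, masks, cfg = toy_filter_inputs
        retained, log = apply_filters(records, read_lengths, masks, cfg)
        assert [r.qseqid for r in retained] == ["r1", "r6"]
        assert log.as_dict() == {"identity": 1, "evalue": 1, "coverage": 1, "mask": 1}

    def test_empty_input(self):
        retained, log = apply_filters([], {}, {}, FilterConfig())
        assert retained == [] and log.n_input == 0
        assert sum(log.as_dict().values()) == 0

    def test_thresholds_are_inclusive(self):
        cfg = FilterConfig()
        rec = make_alignment("r1", pident=50.0, qstart=1, qend=90, evalue=1e-4)
        retained, _ = apply_filters([rec], {"r1": 100}, {}, cfg)
        assert retained == [rec]

    def test_missing_read_length_is_an_error(self):
        with pytest.raises(KeyError, match="r1"):
            apply_filters([make_alignment("r1")], {}, {}, FilterConfig())

    def test_mask_requires_one_bp_overlap(self):
        cfg = FilterConfig()
        masks = {"A": [(1000, 1100)]}
        touching = make_alignment("r1", sstart=1101, qend=100)  # internal [1100, 1200)
        overlapping = make_alignment("r2", sstart=1100, qend=100)  # internal [1099, 1199)
        retained, log = apply_filters(
            [touching, overlapping], {"r1": 100, "r2": 100}, masks, cfg
        )
        assert [r.qseqid for r in retained] == ["r1"]
        assert log.as_dict()["mask"] == 1

    @given(st.data())
    def test_rules_commute(self, data):
        """The retained set equals the intersection of the single-rule sets."""
        n = data.draw(st.integers(2, 12))
        records = []
        for i in range(n):
            records.append(
                make_alignment(
                    f"r{i}",
                    pident=data.draw(st.floats(30, 100)),
                    qstart=1,
                    qend=data.draw(st.integers(50, 100)),
                    sstart=data.draw(st.integers(1, 1900)),
                    evalue=data.draw(st.sampled_from([1e-50, 1e-5, 1e-3, 0.1])),
                )
            )
        read_lengths = {r.qseqid: 100 for r in records}
        masks = {"A": [(500, 700)]}
        cfg = FilterConfig()
        combined, _ = apply_filters(records, read_lengths, masks, cfg)

        neutral = dict(min_pident=0.0, max_evalue=float("inf"),
                       min_query_coverage=1e-9, population_identity=100.0)
        single = []
        for override in (
            {"min_pident": cfg.min_pident, "population_identity": 100.0},
            {"max_evalue": cfg.max_evalue},
            {"min_query_coverage": cfg.min_query_coverage},
        ):
            only, _ = apply_filters(records, read_lengths, {}, FilterConfig(**{**neutral, **override}))
            single.append({r.qseqid for r in only})
        only_mask, _ = apply_filters(records, read_lengths, masks, FilterConfig(**neutral))
        single.append({r.qseqid for r in only_mask})
        assert {r.qseqid for r in combined} == set.intersection(*single)


class TestCompetitiveAssign:
    def test_closest_hit_wins(self):
        a = make_alignment("r1", genome_id="A", bitscore=180.0)
        b = make_alignment("r1", genome_id="B", bitscore=150.0)
        (result,) = assigned([a, b])
        assert result.genome_id == "A" and not result.ambiguous

    def test_single_genome_read_assigned(self):
        (result,) = assigned([make_alignment("r2", genome_id="B")])
        assert result.genome_id == "B"

    def test_full_tie_is_ambiguous(self):
        a = make_alignment("r3", genome_id="A", bitscore=180.0, pident=99.0)
        b = make_alignment("r3", genome_id="B", bitscore=180.0, pident=99.0)
        (result,) = assigned([a, b])
        assert result.ambiguous and result.genome_id is None

    def test_bitscore_tie_broken_by_pident(self):
        a = make_alignment("r4", genome_id="A", bitscore=180.0, pident=98.0)
        b = make_alignment("r4", genome_id="B", bitscore=180.0, pident=99.0)
        (result,) = assigned([a, b])
        assert result.genome_id == "B"


class TestGenomeRecovery:
    def test_union_of_intervals(self):
        cfg = FilterConfig()
        reads = assigned(
            [
                make_alignment("r1", pident=99.0, sstart=1, qend=50, send=50),
                make_alignment("r2", pident=99.0, sstart=41, qend=20, send=60),
            ]
        )
        covered, pct = genome_recovery(reads, 100, cfg)
        assert (covered, pct) == (60, 60.0)

    def test_no_reads_means_zero(self):
        assert genome_recovery([], 100, FilterConfig()) == (0, 0.0)

    def test_population_threshold_is_strict(self):
        reads = assigned([make_alignment("r1", pident=95.0, sstart=1, qend=50, send=50)])
        covered, pct = genome_recovery(reads, 100, FilterConfig())
        assert (covered, pct) == (0, 0.0)

    def test_interval_outside_genome_rejected(self):
        reads = assigned([make_alignment("r1", pident=99.0, sstart=90, qend=50, send=139)])
        with pytest.raises(ValueError):
            genome_recovery(reads, 100, FilterConfig())

    @given(st.lists(st.tuples(st.integers(0, 180), st.integers(1, 20), st.floats(90, 100)),
                    min_size=0, max_size=15))
    def test_matches_boolean_mask_oracle(self, triples):
        cfg = FilterConfig()
        reads = []
        mask = np.zeros(200, dtype=bool)
        for i, (start, span, pident) in enumerate(triples):
            end = min(start + span, 200)
            reads.append(
                make_alignment(f"r{i}", pident=pident, sstart=start + 1, qend=end - start, send=end)
            )
            if pident > cfg.population_identity:
                mask[start:end] = True
        covered, _ = genome_recovery(assigned(reads), 200, cfg)
        assert covered == int(mask.sum())


class TestIdentityHistogram:
    def test_binning_worked_example(self):
        cfg = FilterConfig()
        reads = assigned(
            [
                make_alignment("r1", pident=99.5, sstart=1),
                make_alignment("r2", pident=99.2, sstart=201),
                make_alignment("r3", pident=83.0, sstart=401),
            ]
        )
        hist = identity_histogram(reads, cfg)
        assert hist.counts[-1] == 2  # both 99.x reads in the closed [99, 100] bin
        assert hist.counts[int(83 - 70)] == 1  # the [83, 84) bin
        assert hist.counts.sum() == 3 and hist.underflow == 0
        assert hist.total == 3

    def test_top_bin_closed_and_underflow(self):
        cfg = FilterConfig()
        reads = assigned(
            [
                make_alignment("r1", pident=100.0, sstart=1),
                make_alignment("r2", pident=69.9, sstart=201),
            ]
        )
        hist = identity_histogram(reads, cfg)
        assert hist.counts[-1] == 1
        assert hist.underflow == 1
        assert hist.total == 2


class TestNaiveAligner:
    def test_error_free_read_found_at_true_interval(self, small_pair):
        rs = simulate_reads(small_pair, ReadSimConfig(n_reads=20, mode="MG", error_rate=0.0, seed=21))
        records = align_reads_naive(rs.reads, small_pair.genomes)
        by_key = {(r.qseqid, r.genome_id): r for r in records}
        for truth in rs.truth:
            rec = by_key[(truth.read_id, truth.origin_lineage)]
            assert rec.pident == 100.0
            assert (rec.subject_start, rec.subject_end) == (
                truth.origin_start, truth.origin_end,
            )

    def test_agrees_with_truth_alignments_when_seeded(self, small_pair):
        rs = simulate_reads(small_pair, ReadSimConfig(n_reads=50, mode="MG", error_rate=0.01, seed=22))
        naive = {(r.qseqid, r.genome_id): r for r in align_reads_naive(rs.reads, small_pair.genomes)}
        truth = {(r.qseqid, r.genome_id): r for r in rs.truth_alignments}
        hits = 0
        for key, nrec in naive.items():
            trec = truth[key]
            if nrec.sstart == trec.sstart:  # found the true diagonal
                assert nrec.pident == trec.pident
                assert nrec.mismatch == trec.mismatch
                hits += 1
        assert hits > 0

    def test_random_read_does_not_crash(self, small_pair):
        rng = np.random.default_rng(0)
        from symbiorecruit import SequenceRecord

        read = SequenceRecord(id="junk", residues="".join(rng.choice(list("ACGT"), 100)))
        align_reads_naive([read], small_pair.genomes)  # typically no record

    def test_seed_longer_than_read_rejected(self, small_pair):
        from symbiorecruit import SequenceRecord

        read = SequenceRecord(id="short", residues="ACGTACGT")
        with pytest.raises(ValueError):
            align_reads_naive([read], small_pair.genomes, k=13)


class TestEndToEnd:
    def test_error_free_assignment_recovers_origin(self, small_pair):
        """With no sequencing error, every read whose span contains a
        divergent site is unambiguous and assigned to its origin."""
        rs = simulate_reads(
            small_pair,
            ReadSimConfig(n_reads=2_000, mode="MG", error_rate=0.0, seed=23),
        )
        res = recruit(rs.truth_alignments, rs.read_lengths, small_pair.masks, small_pair.genome_lengths)
        truth = {t.read_id: t for t in rs.truth}
        variants = small_pair.variant_positions
        for a in res.assigned:
            t = truth[a.read_id]
            n_var = np.searchsorted(variants, t.origin_end) - np.searchsorted(variants, t.origin_start)
            if n_var >= 1:
                assert not a.ambiguous
                assert a.genome_id == t.origin_lineage
            else:
                assert a.ambiguous

    def test_bookkeeping(self, small_pair):
        rs = simulate_reads(small_pair, ReadSimConfig(n_reads=1_000, mode="MG", seed=24))
        res = recruit(rs.truth_alignments, rs.read_lengths, small_pair.masks, small_pair.genome_lengths)
        n_assigned = sum(s.n_assigned for s in res.summaries.values())
        assert n_assigned + res.n_ambiguous == len(res.assigned)
        # each summary's histogram accounts for every assigned read
        for s in res.summaries.values():
            assert s.histogram.total == s.n_assigned
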