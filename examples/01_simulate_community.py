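"""Simulate a two-lineage symbiont community with ground truth.

Builds an ancestor genome, diverges two lineages from it at 5 % expected
pairwise divergence, lays down gene / rRNA / ITS annotations, and draws a
small metagenome sample with per-base sequencing error.  Prints the
realised divergence (which the truth records make exactly knowable) and
the structure of the simulated sample.
"""

from collections import Counter

from symbiorecruit import CommunityConfig, ReadSimConfig, simulate_genome_pair, simulate_reads

pair = simulate_genome_pair(CommunityConfig(genome_length=50_000, n_genes=40, seed=1,
                                            rrna_intervals=((46_000, 48_000),),
                                            its_intervals=((48_000, 48_300),)))
print(f"genome length: {pair.genome_length} bp, genes: {len(pair.genes)}")
print(f"expected divergence: {pair.config.divergence:.3f}, "
      f"realised: {pair.realized_divergence:.4f} "
      f"({len(pair.variant_positions)} variant sites)")
print("masked intervals (rRNA/ITS):", pair.masks["A"])

reads = simulate_reads(
    pair,
    ReadSimConfig(n_reads=2_000, mode="MG", lineage_weights={"A": 0.8, "B": 0.2},
                  error_rate=0.01, seed=2),
)
origins = Counter(t.origin_lineage for t in reads.truth)
errors = Counter(t.n_errors for t in reads.truth)
print(f"\nsimulated {len(reads.reads)} MG reads; origins: {dict(origins)}")
print(f"reads with 0/1/2 errors: {errors[0]}/{errors[1]}/{errors[2]} "
      "(per-base error 0.01, so ~37/37/18 % expected)")
print("each read carries an exact truth alignment against BOTH genomes,")
print("so the downstream pipeline runs with no external aligner.")
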