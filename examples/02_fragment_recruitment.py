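"""Competitive fragment recruitment against two closely related genomes.

Simulates a mixed sample, filters alignments exactly as the recruitment
protocol prescribes (identity >= 50 %, e-value <= 1e-4, >= 90 % of the
read aligned, rRNA/ITS masked), assigns each read to its closest-hit
genome by bitscore, and reports the population read counts and the
breadth-of-coverage genome recovery per genome — the statistic that, on
real samples, distinguishes in which size fraction each lineage lives.
"""

from symbiorecruit import CommunityConfig, ReadSimConfig, recruit, simulate_genome_pair, simulate_reads

pair = simulate_genome_pair(CommunityConfig(seed=5))
sample = simulate_reads(
    pair,
    ReadSimConfig(n_reads=10_000, mode="MG", lineage_weights={"A": 0.9, "B": 0.1},
                  error_rate=0.005, seed=6),
)
result = recruit(sample.truth_alignments, sample.read_lengths, pair.masks, pair.genome_lengths)

log = result.filter_log
print(f"alignments in: {log.n_input}, retained: {log.n_retained}, removed: {log.as_dict()}")
print(f"ambiguous reads (tied between genomes): {result.n_ambiguous}\n")
for genome, s in sorted(result.summaries.items()):
    print(f"genome {genome}: {s.n_assigned} reads assigned, "
          f"{s.n_population} above the 95 % population threshold, "
          f"recovery {s.recovery_pct:.2f} % of {s.genome_length} bp")
truth = {t.read_id: t.origin_lineage for t in sample.truth}
unamb = [a for a in result.assigned if not a.ambiguous]
acc = sum(a.genome_id == truth[a.read_id] for a in unamb) / len(unamb)
print(f"\nassignment accuracy vs simulator truth: {100 * acc:.2f} %")
print("genome A dominates the mixture (90 % of reads), so its recovery is")
print("near the Lander-Waterman expectation for ~4.5x coverage while B,")
print("at ~0.5x, recovers far less of its genome.")
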