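# Methods

This note documents the models, conventions and parameter choices behind
symbiorecruit: what each stage assumes, which knobs matter, what the
synthetic community does and does not emulate, and where the design was
genuinely open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open `[start, end)`;
conversion to the 1-based inclusive conventions of GFF3 and BLAST
tabular output happens only at file boundaries.  Minus-strand subject
alignments (`sstart > send`) are normalised to subject-forward intervals
with the strand kept as a flag.  The mapping from subject (contig) ids to
genome ids is an explicit user-supplied table rather than a prefix
heuristic, so multi-contig assemblies work unchanged.

## Fragment recruitment

A read may produce several HSPs per genome; only the best
(highest bitscore, ties by higher identity, then smallest subject
coordinates) enters filtering.  The four filter rules are applied as:

| rule      | condition to keep                        | default |
|-----------|------------------------------------------|---------|
| identity  | pident ≥ min_pident                      | 50 %    |
| e-value   | evalue ≤ max_evalue                      | 1e-4    |
| coverage  | (qend − qstart + 1)/read_length ≥ c      | 0.90    |
| mask      | no rRNA/ITS overlap of ≥ 1 bp            | —       |

Conventions worth noting, each configurable:

* **Inclusive filter boundaries, strict population threshold.**  The
  filter thresholds keep records *at* the boundary (≥ 50 %, ≤ 1e-4,
  ≥ 90 %), whereas the population-identity rule used for recovery,
  histograms above the population line and per-gene counting is strict
  (> 95 %).  This follows the usual phrasing of the protocol ("excluded
  … < 90 %" vs "> 95 % identity").
* **Query coverage uses the query span**, not the alignment-length
  column, making it robust to gap columns.
* **Any mask overlap excludes a record.**  Whether rRNA/ITS reads should
  be removed by positional overlap or by independent classification is an
  open point in recruitment protocols; positional overlap with a 1 bp
  threshold is the conservative choice.
* **Recovery denominator is the full genome length**, masked regions
  included, so a genome with 2.5 % of its length masked cannot exceed
  ~97.5 % recovery.  This keeps recovery comparable across genomes with
  different mask fractions.
* **Ties.**  A read whose best hits to both genomes tie on bitscore and
  identity is *ambiguous*: counted separately and excluded from both
  genomes' summaries, since no closest hit exists.

Competitive assignment picks the genome with the highest-bitscore
retained hit (ties by identity).  The identity histogram uses 1 % bins on
[70, 100] with a closed top bin and an underflow bin, so counts always
sum to the number of assigned reads.

`align_reads_naive` is a deliberately simple exact-k-mer-seeded, ungapped
aligner (k = 13, every k-th read k-mer seeds a diagonal) for the no-indel
synthetic regime, so end-to-end runs need no external aligner.  It is not
a BLAST replacement: reads whose every seed window contains an error can
be missed, and indels are not modelled.

## Expression profiling

A read "covers" a gene if its subject interval overlaps the gene by
≥ 1 bp and its identity exceeds the population threshold.  With 100 bp
reads against ~900 bp genes, any-overlap and full-containment counting
differ by ≲ 10 %; any-overlap is the weaker assumption and the one
implemented.  A read spanning two genes counts once for each (no
fractional splitting), so column sums may exceed read counts.

Normalisations:

* **per cell** — mt_count(g) / combine(mt_count over housekeeping genes),
  where combine is the **mean** by default (`sum` and `geometric` are
  available).  The protocol names recA and gyrB without an operator; the
  mean has the convenient identity that the mean of the housekeeping
  genes' own per-cell values is exactly 1, which the tests assert.
  A zero denominator flags all values missing rather than raising.
* **metagenome-normalised** — (mt/mt_depth)/(mg/mg_depth) per gene;
  zero MG coverage flags the gene missing, zero MT with observed MG is a
  true 0.

Cluster contributions are percentages of the *total* transcript pool of
the genome (not of the labelled clusters only), so contributions sum to
≤ 100.  Cross-sample regression is ordinary least squares of a cluster's
counts on the nif-operon counts with a two-sided t-test on the slope
(n − 2 df); a constant response returns slope 0, R² 0, p 1, and zero
variance in the predictor is an error.

## Ka/Ks and the codon-based Z-test

Sites: for each sense codon, each of the nine single-nucleotide mutants
contributes 1/3 of a site, synonymous or nonsynonymous by the standard
genetic code.  Differences: codons differing at k positions are averaged
uniformly over the k! substitution orderings; orderings passing through a
stop codon are excluded and the rest re-weighted (with a flagged uniform
fallback if every ordering is blocked).  S and N are averaged over the
two sequences; pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), with p ≥ 3/4 flagged as saturated.

**Stop-codon site policy.**  Mutant channels that create stop codons are,
by default, excluded from both S and N (`stop_policy="excluded"`), for
internal consistency: the difference counter never realises a pathway
through a stop, and any stop-avoiding substitution process cannot use
those channels, so counting them as nonsynonymous *sites* deflates dN.
Measured on the package's own neutral simulator (ω = 1, 500 codons,
B = 200), the excluded policy gives an unbiased ω estimate (median 1.00)
and a calibrated one-tailed test (empirical size 0.058 at α = 0.05),
whereas counting stops as nonsynonymous gives median ω 0.93 and size
0.13.  The `nonsynonymous` policy remains available as a toggle and is
the convention of Biopython's NG86 implementation, against which the
package is cross-checked exactly in the test suite.

The Z statistic is (dS − dN)/√(Var dS + Var dN).  The default variance is
a seeded bootstrap over codon columns (B = 1000 in the API, B = 200 in
the batch screens below); the analytic alternative propagates binomial
variances of pS and pN through the Jukes–Cantor transform (delta method).
The test is one-tailed for purifying selection (dN < dS) by default, with
`positive` and `two_sided` alternatives.  Degenerate pairs (identical
sequences, zero variance, saturation) return p = 1 with a flag.  The
genome summary applies no multiple-testing correction.

Ortholog identification and codon alignment are out of scope: inputs are
pre-aligned in-frame pairs (paired FASTA `<gene>|1` / `<gene>|2`), which
the simulator provides and an external aligner can supply for real
genomes.

## The synthetic community

The generator's defaults define the study conditions the tests probe:

| parameter | default | rationale |
|-----------|---------|-----------|
| genome_length | 200 kb | small-symbiont scale, fast to simulate |
| n_genes × gene_length | 150 × 900 bp | typical prokaryotic gene length and density |
| divergence | 0.05 | "closely related lineages" regime: ~5 divergent sites per 100 bp read, so most reads are discriminable but a measurable fraction is not; the real lineage pair's genome-wide identity is not published, so this is a configurable stand-in |
| gc_content | 0.35 | AT-rich, as reduced symbiont genomes tend to be |
| error_rate | 0.005 | short-read substitution-error scale; 0.01 in stress tests |
| read_length | 100 bp | the short-read chemistry the protocol assumes |
| nif operon mass | 0.25 | the nitrogen-fixation-dominated profile: a quarter of all transcripts |
| other cluster masses | ATP synthase 0.12, cyt b6f 0.08, PSI 0.15, housekeeping 0.04 | highly transcribed energy machinery plus a baseline; remainder uniform over unlabelled genes |
| expected_dS (codon sim) | 0.3 | mid-range divergence: well away from both zero information and saturation |

Lineages A and B each substitute every ancestral site independently with
probability divergence/2, uniformly over the three alternatives
(Jukes–Cantor-like), with no indels and no rate heterogeneity, so
annotations carry over at identical coordinates and ungapped full-length
truth alignments against *both* genomes are exact.  MT reads are wholly
contained in their gene; genes shorter than the read length are excluded
from the expression weights (with a warning).  The bitscore surrogate is
2·matches − 3·mismatches and the e-value surrogate 10^(−bitscore/10);
only their ordering matters downstream.  The codon-pair evolver proposes
single-nucleotide codon changes, accepts synonymous ones with probability
1 and nonsynonymous with probability ω (scaled to 1/ω on the synonymous
side when ω > 1), rejects stops, and stops once the accepted synonymous
events reach S(ancestor)·expected_dS.

What the simulator does **not** emulate — hence what passing tests do not
show about real data: indels and gapped alignment, rate heterogeneity
along the genome, transition/transversion bias, quality scores, chimeras
and duplicates, strand-specific library artefacts, rRNA *reads* (only the
masked intervals are placed), and real inter-genome rearrangements.  The
recruitment thresholds were designed for BLAST HSPs; the simulator's
full-length alignments make the coverage and e-value filters almost
always pass, so those rules are exercised mainly by the hand-built
worked-example tables.

## Determinism and problem sizes

Every simulator takes an explicit seed; the pipeline derives per-stage,
per-item seeds from one global seed via numpy `SeedSequence([seed,
stage, item])`, so a single integer reproduces a whole run byte-for-byte
(fixed float formatting, sorted JSON manifest; the output directory is
not echoed into the manifest).  The test suite and the acceptance script
run the statistical checks at deliberately modest sizes chosen as the
package's own working scale — e.g. 20 oracle instances of 1,000 reads on
200 kb genomes, 10,000-read discrimination runs, 1,000 neutral pairs of
500 codons at B = 200 for test calibration, 200 pairs of 1,000 codons for
power — sizes at which the binomial tolerances quoted in the tests are
meaningful.

## Known limitations

* Genome recovery and per-gene counting assume ungapped subject
  intervals; spliced or clipped alignments would need their aligned
  blocks split upstream.
* The naive aligner is a convenience for the synthetic regime, not a
  production mapper.
* NG86 with Jukes–Cantor correction underestimates distances under
  strong transition bias; a codeml-style ML estimate is out of scope.
* The per-cell normalisation approximates transcripts per cell only to
  the extent that the housekeeping genes are single-copy and uniformly
  expressed — true in the simulator by construction, an assumption on
  real data.
* File-driven (non-synthetic) runs cover the recruitment stage; the
  expression stage requires the paired-sample structure the simulator or
  a config provides.
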