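"""Competitive fragment recruitment against two closely related reference genomes.

The stages mirror the standard recruitment workflow: reduce multiple HSPs
to one best hit per (read, genome); filter on identity, e-value, query
coverage and rRNA/ITS masks; assign each read to its closest-hit genome by
bitscore; then summarise each genome's population (reads above the
population-identity threshold), breadth-of-coverage genome recovery, and
the percent-identity histogram.

Threshold conventions (documented, configurable): the identity, e-value
and query-coverage filters are inclusive (>= 50 %, <= 1e-4, >= 90 % of the
read length); the population-identity threshold is strict (> 95 %).  Any
mask overlap of >= 1 bp excludes a record.  The recovery denominator is
the full genome length, masked regions included.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord, TabularAlignmentRecord

__all__ = [
    "FilterConfig",
    "FilterLog",
    "AssignedRead",
    "Histogram",
    "RecruitmentSummary",
    "RecruitmentResult",
    "best_hit_per_genome",
    "apply_filters",
    "competitive_assign",
    "genome_recovery",
    "identity_histogram",
    "summarize_genome",
    "recruit",
    "align_reads_naive",
]

FILTER_RULES = ("identity", "evalue", "coverage", "mask")


@dataclass(frozen=True)
class FilterConfig:
    """Filtering and summary thresholds for fragment recruitment."""

    min_pident: float = 50.0
    max_evalue: float = 1e-4
    min_query_coverage: float = 0.90
    population_identity: float = 95.0
    histogram_lo: float = 70.0
    histogram_hi: float = 100.0
    histogram_step: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_pident <= self.population_identity <= 100.0):
            raise ValueError(
                "need 0 <= min_pident <= population_identity <= 100, got "
                f"{self.min_pident} / {self.population_identity}"
            )
        if not (0.0 < self.min_query_coverage <= 1.0):
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        nbins = (self.histogram_hi - self.histogram_lo) / self.histogram_step
        if self.histogram_hi <= self.histogram_lo or abs(nbins - round(nbins)) > 1e-9:
            raise ValueError("histogram range must be a whole number of steps")

    @property
    def n_bins(self) -> int:
        return int(round((self.histogram_hi - self.histogram_lo) / self.histogram_step))


@dataclass
class FilterLog:
    """Removals attributed to the first failing rule, in declared order."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in FILTER_RULES}
    )

    def as_dict(self) -> dict[str, int]:
        return dict(self.removed)


@dataclass(frozen=True)
class AssignedRead:
    """One read after competitive assignment.  Ambiguous (fully tied) reads
    carry no genome and are excluded from per-genome summaries."""

    read_id: str
    genome_id: str | None
    record: TabularAlignmentRecord | None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.ambiguous:
            if self.genome_id is not None:
                raise ValueError("ambiguous reads carry no genome_id")
        else:
            if self.record is None or self.record.genome_id != self.genome_id:
                raise ValueError("assigned record must match genome_id")


@dataclass
class Histogram:
    """Identity histogram: bins [lo + k*step, lo + (k+1)*step) with the top
    bin closed at hi; identities below lo fall in the underflow bin."""

    lo: float
    hi: float
    step: float
    counts: np.ndarray
    underflow: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.underflow

    def bin_edges(self) -> np.ndarray:
        return self.lo + self.step * np.arange(len(self.counts) + 1)

    def as_frame(self) -> pd.DataFrame:
        edges = self.bin_edges()
        rows = [
            {"bin_lo": float("-inf"), "bin_hi": self.lo, "count": self.underflow}
        ]
        for i, c in enumerate(self.counts):
            rows.append(
                {"bin_lo": edges[i], "bin_hi": edges[i + 1], "count": int(c)}
            )
        return pd.DataFrame(rows)


@dataclass
class RecruitmentSummary:
    """Per (sample, genome) recruitment summary."""

    genome_id: str
    n_assigned: int
    n_population: int  # assigned reads with pident above the population threshold
    covered_positions: int
    genome_length: int
    recovery_pct: float
    histogram: Histogram
    filter_log: FilterLog | None = None


@dataclass
class RecruitmentResult:
    summaries: dict[str, RecruitmentSummary]
    assigned: list[AssignedRead]
    filter_log: FilterLog
    n_ambiguous: int


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def _hit_rank(r: TabularAlignmentRecord) -> tuple:
    # higher bitscore, then higher pident, then smallest (sstart, send)
    return (r.bitscore, r.pident, -r.sstart, -r.send)


def best_hit_per_genome(
    records: Iterable[TabularAlignmentRecord],
) -> list[TabularAlignmentRecord]:
    """Keep, for each (read, genome), the single best HSP.

    Best = highest bitscore; ties broken by higher percent identity, then
    lexicographically smallest (sstart, send).  Output preserves the order
    of first appearance of each (read, genome) key.
    """
    best: dict[tuple[str, str], TabularAlignmentRecord] = {}
    for r in records:
        key = (r.qseqid, r.genome_id)
        cur = best.get(key)
        if cur is None or _hit_rank(r) > _hit_rank(cur):
            best[key] = r
    return list(best.values())


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[list[int], list[int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [m[0] for m in merged], [m[1] for m in merged]


def _overlaps_mask(starts: list[int], ends: list[int], s: int, e: int) -> bool:
    # merged, sorted, non-overlapping intervals: the only candidate is the
    # last interval starting before e
    i = bisect_left(starts, e)
    return i > 0 and ends[i - 1] > s


def apply_filters(
    records: Iterable[TabularAlignmentRecord],
    read_lengths: Mapping[str, int],
    masks: Mapping[str, Sequence[tuple[int, int]]],
    cfg: FilterConfig,
) -> tuple[list[TabularAlignmentRecord], FilterLog]:
    """Retain records passing all four rules; attribute each removal to the
    first failing rule in the order identity, evalue, coverage, mask.

    A record passes iff pident >= min_pident, evalue <= max_evalue,
    (qend - qstart + 1) / read_length >= min_query_coverage, and its
    subject interval overlaps no rRNA/ITS mask interval by >= 1 bp.
    The retained *set* is order-independent (the rules commute); only the
    log attribution depends on the declared order.
    """
    merged = {g: _merge_intervals(iv) for g, iv in masks.items()}
    log = FilterLog()
    retained: list[TabularAlignmentRecord] = []
    for r in records:
        log.n_input += 1
        if r.qseqid not in read_lengths:
            raise KeyError(f"no read length known for read {r.qseqid!r}")
        if r.pident < cfg.min_pident:
            log.removed["identity"] += 1
            continue
        if r.evalue > cfg.max_evalue:
            log.removed["evalue"] += 1
            continue
        if r.query_span / read_lengths[r.qseqid] < cfg.min_query_coverage:
            log.removed["coverage"] += 1
            continue
        starts, ends = merged.get(r.genome_id, ([], []))
        if starts and _overlaps_mask(starts, ends, r.subject_start, r.subject_end):
            log.removed["mask"] += 1
            continue
        retained.append(r)
    log.n_retained = len(retained)
    return retained, log


def competitive_assign(
    records: Iterable[TabularAlignmentRecord],
) -> list[AssignedRead]:
    """Assign each read to the genome of its closest hit.

    Highest bitscore wins; bitscore ties are broken by higher percent
    identity; a full tie on both makes the read ambiguous.  Reads present
    against a single genome are assigned to it.  Deterministic: output in
    order of first appearance of each read.
    """
    by_read: dict[str, list[TabularAlignmentRecord]] = {}
    for r in records:
        by_read.setdefault(r.qseqid, []).append(r)
    out: list[AssignedRead] = []
    for read_id, hits in by_read.items():
        best_key = max((h.bitscore, h.pident) for h in hits)
        top = [h for h in hits if (h.bitscore, h.pident) == best_key]
        top_genomes = {h.genome_id for h in top}
        if len(top_genomes) > 1:
            out.append(AssignedRead(read_id=read_id, genome_id=None, record=None, ambiguous=True))
        else:
            winner = min(top, key=lambda h: (h.sstart, h.send))
            out.append(
                AssignedRead(read_id=read_id, genome_id=winner.genome_id, record=winner)
            )
    return out


def genome_recovery(
    assigned: Sequence[AssignedRead], genome_length: int, cfg: FilterConfig
) -> tuple[int, float]:
    """Breadth-of-coverage recovery for one genome.

    Takes the subject intervals of assigned reads with identity strictly
    above the population threshold, unions them, and reports
    (covered_positions, 100 * covered / genome_length).  The denominator is
    the full genome length, masked regions included.
    """
    intervals = []
    for a in assigned:
        if a.ambiguous or a.record is None:
            continue
        if a.record.pident > cfg.population_identity:
            s, e = a.record.subject_start, a.record.subject_end
            if s < 0 or e > genome_length:
                raise ValueError(
                    f"read {a.read_id!r}: subject interval [{s}, {e}) outside "
                    f"genome of length {genome_length}"
                )
            intervals.append((s, e))
    if not intervals:
        return 0, 0.0
    starts, ends = _merge_intervals(intervals)
    covered = sum(e - s for s, e in zip(starts, ends))
    return covered, 100.0 * covered / genome_length


def identity_histogram(assigned: Sequence[AssignedRead], cfg: FilterConfig) -> Histogram:
    """Bin assigned-read identities at ``histogram_step`` percent over
    [histogram_lo, histogram_hi]; the top bin is closed, identities below
    the range go to the underflow bin.  Counts (plus underflow) sum to the
    number of assigned reads."""
    counts = np.zeros(cfg.n_bins, dtype=int)
    underflow = 0
    for a in assigned:
        if a.ambiguous or a.record is None:
            continue
        p = a.record.pident
        if p < cfg.histogram_lo:
            underflow += 1
            continue
        idx = int((p - cfg.histogram_lo) // cfg.histogram_step)
        if idx >= cfg.n_bins:  # p == histogram_hi: closed top bin
            idx = cfg.n_bins - 1
        counts[idx] += 1
    return Histogram(
        lo=cfg.histogram_lo,
        hi=cfg.histogram_hi,
        step=cfg.histogram_step,
        counts=counts,
        underflow=underflow,
    )


def summarize_genome(
    genome_id: str,
    assigned: Sequence[AssignedRead],
    genome_length: int,
    cfg: FilterConfig,
    filter_log: FilterLog | None = None,
) -> RecruitmentSummary:
    mine = [a for a in assigned if a.genome_id == genome_id]
    covered, recovery = genome_recovery(mine, genome_length, cfg)
    hist = identity_histogram(mine, cfg)
    n_pop = sum(
        1 for a in mine if a.record is not None and a.record.pident > cfg.population_identity
    )
    return RecruitmentSummary(
        genome_id=genome_id,
        n_assigned=len(mine),
        n_population=n_pop,
        covered_positions=covered,
        genome_length=genome_length,
        recovery_pct=recovery,
        histogram=hist,
        filter_log=filter_log,
    )


def recruit(
    records: Iterable[TabularAlignmentRecord],
    read_lengths: Mapping[str, int],
    masks: Mapping[str, Sequence[tuple[int, int]]],
    genome_lengths: Mapping[str, int],
    cfg: FilterConfig | None = None,
) -> RecruitmentResult:
    """Run the full recruitment stage: best hit per genome -> filters ->
    competitive assignment -> per-genome summaries."""
    cfg = cfg or FilterConfig()
    best = best_hit_per_genome(records)
    retained, log = apply_filters(best, read_lengths, masks, cfg)
    assigned = competitive_assign(retained)
    n_ambiguous = sum(1 for a in assigned if a.ambiguous)
    summaries = {
        g: summarize_genome(g, assigned, glen, cfg, log)
        for g, glen in sorted(genome_lengths.items())
    }
    return RecruitmentResult(
        summaries=summaries, assigned=assigned, filter_log=log, n_ambiguous=n_ambiguous
    )


# ---------------------------------------------------------------------------
# Naive ungapped aligner (stand-in so end-to-end runs need no external tool)
# ---------------------------------------------------------------------------

def align_reads_naive(
    reads: Sequence[SequenceRecord],
    genomes: Mapping[str, SequenceRecord],
    k: int = 13,
) -> list[TabularAlignmentRecord]:
    """Exact k-mer seeded, ungapped full-read alignment of reads against
    each genome (no-indel regime).

    Every k-th k-mer of the read seeds candidate diagonals; each candidate
    diagonal is scored by exact full-read mismatch count and the best
    diagonal per (read, genome) is reported.  Reads with no exact seed
    match on a genome yield no record for it.
    """
    if not reads:
        return []
    min_len = min(len(r) for r in reads)
    if k > min_len:
        raise ValueError(f"seed length k={k} exceeds shortest read length {min_len}")
    indexes: dict[str, dict[str, list[int]]] = {}
    for gid, genome in genomes.items():
        seq = genome.residues
        index: dict[str, list[int]] = {}
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append(pos)
        indexes[gid] = index

    out: list[TabularAlignmentRecord] = []
    for read in reads:
        rl = len(read)
        rseq = read.residues
        for gid in sorted(genomes):
            genome = genomes[gid]
            gseq = genome.residues
            L = len(gseq)
            index = indexes[gid]
            diagonals: set[int] = set()
            for off in range(0, rl - k + 1, k):
                for pos in index.get(rseq[off : off + k], ()):
                    d = pos - off
                    if 0 <= d <= L - rl:
                        diagonals.add(d)
            best: tuple[int, int] | None = None  # (mismatches, diagonal)
            for d in sorted(diagonals):
                mm = sum(1 for a, b in zip(rseq, gseq[d : d + rl]) if a != b)
                if best is None or mm < best[0]:
                    best = (mm, d)
            if best is None:
                continue
            mm, d = best
            bits = float(2 * (rl - mm) - 3 * mm)
            out.append(
                TabularAlignmentRecord(
                    qseqid=read.id,
                    sseqid=genome.id,
                    pident=100.0 * (1.0 - mm / rl),
                    length=rl,
                    mismatch=mm,
                    gapopen=0,
                    qstart=1,
                    qend=rl,
                    sstart=d + 1,
                    send=d + rl,
                    evalue=10.0 ** (-bits / 10.0) if bits < 200 else 1e-20,
                    bitscore=bits,
                    genome_id=gid,
                )
            )
    return out
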