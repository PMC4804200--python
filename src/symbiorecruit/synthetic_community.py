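"""Ground-truthed synthetic inputs for the recruitment / expression / Ka-Ks pipeline.

The simulator emulates the statistical structure the analysis assumes:

* two closely related symbiont genomes produced by independent site-wise
  substitution from a common ancestor (no indels, so annotations carry
  over at identical coordinates and ungapped truth alignments are exact);
* sequencing samples whose lineage mixture varies (as it does across
  plankton size fractions), with metagenome (MG) reads uniform along the
  genome and metatranscriptome (MT) reads drawn from gene intervals under
  a nitrogen-fixation-operon-dominated expression profile;
* per-base substitution sequencing error;
* in-frame codon-pair alignments evolved at a known dN/dS ratio.

Every simulator is bit-reproducible under a fixed seed and returns the
ground truth (read origins, error counts, exact alignments to both
genomes, substitution event counts) that the test oracles rely on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    AnnotationRecord,
    FormatError,
    SequenceRecord,
    TabularAlignmentRecord,
)
from .selection import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    CodonPairAlignment,
    codon_sites,
)

__all__ = [
    "CommunityConfig",
    "ReadSimConfig",
    "CodonSimConfig",
    "TruthRecord",
    "GenomePair",
    "ReadSet",
    "CodonSimTruth",
    "simulate_genome_pair",
    "simulate_reads",
    "simulate_codon_pair",
    "default_expression_weights",
]

LINEAGES = ("A", "B")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

# gene-cluster blocks laid down along the genome, in order; the two
# housekeeping genes are the single-copy normalisation anchors
_CLUSTER_BLOCKS: tuple[tuple[str | None, tuple[str, ...]], ...] = (
    ("housekeeping", ("recA", "gyrB")),
    ("nif_operon", ("nifB", "nifS", "nifU", "nifH", "nifD", "nifK", "nifE", "nifN", "nifX")),
    ("atp_synthase", ("atpB", "atpE", "atpF", "atpH", "atpA", "atpG", "atpD", "atpC")),
    ("cyt_b6f", ("petA", "petB", "petC", "petD", "petG", "petM")),
    ("PSI", ("psaA", "psaB", "psaC", "psaD", "psaE", "psaF", "psaI", "psaJ", "psaK", "psaL", "psaM")),
)

DEFAULT_CLUSTER_MASSES: dict[str, float] = {
    "nif_operon": 0.25,
    "atp_synthase": 0.12,
    "cyt_b6f": 0.08,
    "PSI": 0.15,
    "housekeeping": 0.04,
}


class SimulationError(RuntimeError):
    """The requested simulation cannot be realised under the given config."""


def _check_intervals(intervals: Sequence[tuple[int, int]], genome_length: int, what: str) -> None:
    for s, e in intervals:
        if not (0 <= s < e <= genome_length):
            raise SimulationError(f"{what} interval [{s}, {e}) outside genome [0, {genome_length})")


def _merged(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            raise SimulationError(f"overlapping masked intervals at [{s}, {e})")
        out.append((s, e))
    return out


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the two-lineage synthetic community.

    ``divergence`` is the expected per-site substitution fraction on the
    path between the two lineages (each lineage diverges from the common
    ancestor at ``divergence / 2``).
    """

    genome_length: int = 200_000
    n_genes: int = 150
    gene_length: int = 900
    divergence: float = 0.05
    gc_content: float = 0.35
    rrna_intervals: tuple[tuple[int, int], ...] = ((190_000, 194_500),)
    its_intervals: tuple[tuple[int, int], ...] = ((194_500, 195_000),)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.3):
            raise SimulationError(f"divergence {self.divergence} outside [0, 0.3]")
        if not (0.0 < self.gc_content < 1.0):
            raise SimulationError("gc_content must be in (0, 1)")
        if self.gene_length <= 0 or self.n_genes <= 0 or self.genome_length <= 0:
            raise SimulationError("genome_length, n_genes, gene_length must be positive")
        _check_intervals(self.rrna_intervals, self.genome_length, "rRNA")
        _check_intervals(self.its_intervals, self.genome_length, "ITS")
        _merged([*self.rrna_intervals, *self.its_intervals])  # non-overlap check


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of one simulated sequencing sample."""

    n_reads: int
    mode: str = "MG"  # MG: uniform genomic; MT: gene-interval reads
    read_length: int = 100
    lineage_weights: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.5, "B": 0.5}
    )
    error_rate: float = 0.005
    expression_weights: Mapping[str, float] | None = None
    seed: int = 0
    read_id_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("MG", "MT"):
            raise SimulationError(f"mode must be MG or MT, got {self.mode!r}")
        if self.n_reads <= 0 or self.read_length <= 0:
            raise SimulationError("n_reads and read_length must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise SimulationError("error_rate must be in [0, 1)")
        total = sum(self.lineage_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"lineage_weights sum to {total}, expected 1")


@dataclass(frozen=True)
class CodonSimConfig:
    """Parameters of the codon-pair evolver (known dN/dS ground truth)."""

    n_codons: int
    omega: float = 0.2
    expected_dS: float = 0.3
    seed: int = 0
    gene_id: str = "pair"
    max_proposals: int | None = None

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise SimulationError("omega must be > 0")
        if self.n_codons < 10:
            raise SimulationError("n_codons must be >= 10")
        if self.expected_dS < 0:
            raise SimulationError("expected_dS must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    origin_lineage: str
    origin_start: int  # 0-based half-open on the origin genome
    origin_end: int
    n_errors: int

    @property
    def true_identity_to_origin(self) -> float:
        return 100.0 * (1.0 - self.n_errors / (self.origin_end - self.origin_start))


@dataclass
class GenomePair:
    """A simulated ancestor and two diverged lineage genomes.

    Annotations are stored once (the lineages are perfectly syntenic, with
    no indels); ``annotations_for`` re-labels them for a given genome.
    """

    config: CommunityConfig
    ancestor: SequenceRecord
    genomes: dict[str, SequenceRecord]
    annotations: list[AnnotationRecord]
    variant_positions: np.ndarray  # positions where the two lineages differ
    realized_divergence: float
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def genome_length(self) -> int:
        return self.config.genome_length

    @property
    def lineages(self) -> tuple[str, ...]:
        return tuple(sorted(self.genomes))

    def annotations_for(self, genome_id: str) -> list[AnnotationRecord]:
        return [replace(a, seq_id=genome_id) for a in self.annotations]

    @property
    def genes(self) -> list[AnnotationRecord]:
        return [a for a in self.annotations if a.feature_kind == "gene"]

    @property
    def masks(self) -> dict[str, list[tuple[int, int]]]:
        """Per-genome rRNA + ITS intervals (identical coordinates on both)."""
        intervals = [
            (a.start, a.end) for a in self.annotations if a.feature_kind in ("rRNA", "ITS")
        ]
        return {g: sorted(intervals) for g in self.genomes}

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {g: len(rec) for g, rec in self.genomes.items()}

    @property
    def genome_id_map(self) -> dict[str, str]:
        """Contig -> genome map (one single-contig assembly per lineage)."""
        return {rec.id: g for g, rec in self.genomes.items()}

    def encoded(self, genome_id: str) -> np.ndarray:
        if genome_id not in self._encoded:
            seq = self.genomes[genome_id].residues
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.uint8)
            for i, b in enumerate(BASES):
                lut[ord(b)] = i
            self._encoded[genome_id] = lut[arr]
        return self._encoded[genome_id]


@dataclass
class ReadSet:
    """Simulated reads plus full ground truth and exact truth alignments."""

    config: ReadSimConfig
    reads: list[SequenceRecord]
    truth: list[TruthRecord]
    truth_alignments: list[TabularAlignmentRecord]

    @property
    def read_lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.reads}


@dataclass(frozen=True)
class CodonSimTruth:
    """Realised event counts of one codon-pair simulation."""

    syn_events: int
    nonsyn_events: int
    n_proposals: int
    target_syn_events: int
    S_ancestor: float


# ---------------------------------------------------------------------------
# Genome pair
# ---------------------------------------------------------------------------

def _decode(arr: np.ndarray) -> str:
    return _BASE_BYTES[arr].tobytes().decode("ascii")


def _place_genes(cfg: CommunityConfig) -> list[tuple[int, int]]:
    """Evenly space ``n_genes`` gene intervals inside the unmasked genome."""
    masked = _merged([*cfg.rrna_intervals, *cfg.its_intervals])
    free: list[tuple[int, int]] = []
    cursor = 0
    for s, e in masked:
        if s > cursor:
            free.append((cursor, s))
        cursor = e
    if cursor < cfg.genome_length:
        free.append((cursor, cfg.genome_length))
    total_free = sum(e - s for s, e in free)
    need = cfg.n_genes * cfg.gene_length
    if need > total_free:
        raise SimulationError(
            f"cannot place {cfg.n_genes} genes of {cfg.gene_length} bp in "
            f"{total_free} unmasked bp"
        )
    placed: list[tuple[int, int]] = []
    remaining = cfg.n_genes
    for s, e in free:
        if remaining == 0:
            break
        span = e - s
        m = min(remaining, span // cfg.gene_length)
        if m <= 0:
            continue
        local_gap = (span - m * cfg.gene_length) / (m + 1)
        for k in range(m):
            start = s + int(round(local_gap * (k + 1) + cfg.gene_length * k))
            placed.append((start, start + cfg.gene_length))
        remaining -= m
    if remaining > 0:
        raise SimulationError(
            f"could not place all genes ({remaining} left over); "
            "reduce n_genes or gene_length"
        )
    return placed


def _gene_names(n: int) -> list[tuple[str, str | None]]:
    names: list[tuple[str, str | None]] = []
    for label, ids in _CLUSTER_BLOCKS:
        for gid in ids:
            names.append((gid, label))
    k = 1
    while len(names) < n:
        names.append((f"gene_{k:04d}", None))
        k += 1
    return names[:n]


def simulate_genome_pair(config: CommunityConfig) -> GenomePair:
    """Simulate an ancestor and two lineage genomes diverged from it.

    Each lineage substitutes every site independently with probability
    ``divergence / 2``, choosing uniformly among the three alternative
    bases (Jukes–Cantor-like, no rate heterogeneity, no indels).
    Annotations are carried over at identical coordinates.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ancestor = rng.choice(4, size=L, p=probs).astype(np.uint8)

    genomes: dict[str, np.ndarray] = {}
    for lineage in LINEAGES:
        arr = ancestor.copy()
        mask = rng.random(L) < config.divergence / 2.0
        k = int(mask.sum())
        if k:
            shifts = rng.integers(1, 4, size=k).astype(np.uint8)
            arr[mask] = (arr[mask] + shifts) % 4
        genomes[lineage] = arr

    diff = genomes["A"] != genomes["B"]
    variant_positions = np.flatnonzero(diff)
    realized = float(diff.mean())

    gene_intervals = _place_genes(config)
    names = _gene_names(config.n_genes)
    annotations: list[AnnotationRecord] = []
    for i, ((s, e), (gid, label)) in enumerate(zip(gene_intervals, names)):
        annotations.append(
            AnnotationRecord(
                seq_id="genome",
                feature_kind="gene",
                start=s,
                end=e,
                strand="+" if i % 2 == 0 else "-",
                gene_id=gid,
                cluster_label=label,
            )
        )
    for j, (s, e) in enumerate(config.rrna_intervals, start=1):
        annotations.append(
            AnnotationRecord("genome", "rRNA", s, e, "+", f"rrna_{j:02d}")
        )
    for j, (s, e) in enumerate(config.its_intervals, start=1):
        annotations.append(
            AnnotationRecord("genome", "ITS", s, e, "+", f"its_{j:02d}")
        )
    annotations.sort(key=lambda a: a.start)

    return GenomePair(
        config=config,
        ancestor=SequenceRecord(id="ancestor", residues=_decode(ancestor)),
        genomes={
            g: SequenceRecord(id=g, residues=_decode(arr)) for g, arr in genomes.items()
        },
        annotations=annotations,
        variant_positions=variant_positions,
        realized_divergence=realized,
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def default_expression_weights(
    annotations: Sequence[AnnotationRecord],
    *,
    nif_mass: float = 0.25,
    cluster_masses: Mapping[str, float] | None = None,
    read_length: int = 100,
) -> dict[str, float]:
    """Per-gene expression weights with the nif operon holding ``nif_mass``
    of the transcript pool, the other labelled clusters their default
    masses, and the remainder spread uniformly over unlabelled genes.

    Genes shorter than ``read_length`` are excluded (they cannot contain a
    full read).  Mass assigned to an absent cluster is re-assigned to the
    unlabelled pool.  Weights are uniform within a cluster and sum to 1.
    """
    masses = dict(cluster_masses) if cluster_masses is not None else dict(DEFAULT_CLUSTER_MASSES)
    masses["nif_operon"] = nif_mass
    genes = [
        a for a in annotations if a.feature_kind == "gene" and a.length >= read_length
    ]
    if not genes:
        raise SimulationError("no genes long enough to carry a read")
    by_cluster: dict[str | None, list[str]] = {}
    for g in genes:
        by_cluster.setdefault(g.cluster_label, []).append(g.gene_id)
    weights: dict[str, float] = {}
    assigned = 0.0
    for label, mass in masses.items():
        ids = by_cluster.get(label)
        if not ids:
            continue
        for gid in ids:
            weights[gid] = mass / len(ids)
        assigned += mass
    rest_ids = [gid for label, ids in by_cluster.items() if label not in masses or label is None for gid in ids]
    rest_ids = [gid for gid in rest_ids if gid not in weights]
    rest_mass = 1.0 - assigned
    if rest_ids:
        for gid in rest_ids:
            weights[gid] = rest_mass / len(rest_ids)
    else:
        # renormalise over the clusters present
        scale = 1.0 / assigned
        weights = {gid: w * scale for gid, w in weights.items()}
    return weights


def _bitscore(matches: int, mismatches: int) -> float:
    # declared surrogate: only the ordering matters downstream
    return float(2 * matches - 3 * mismatches)


def simulate_reads(pair: GenomePair, config: ReadSimConfig) -> ReadSet:
    """Simulate one sample of reads from the genome pair.

    MG reads start uniformly on ``[0, L - read_length]`` of their origin
    genome; MT reads are wholly contained in a gene drawn from
    ``expression_weights`` with a uniform start inside the gene.  Each base
    is substituted independently with ``error_rate``.  The returned
    ``truth_alignments`` hold, for every read, its full-length ungapped
    alignment against *both* genomes with exact identity and mismatch
    counts, so the whole downstream pipeline can run with no aligner.
    """
    rng = np.random.default_rng(config.seed)
    L = pair.genome_length
    rl = config.read_length
    if rl > L:
        raise SimulationError("read_length exceeds genome_length")
    n = config.n_reads

    lineages = sorted(config.lineage_weights)
    for lin in lineages:
        if lin not in pair.genomes:
            raise SimulationError(f"unknown lineage {lin!r} in lineage_weights")
    w = np.array([config.lineage_weights[lin] for lin in lineages], dtype=float)
    w = w / w.sum()
    origins = rng.choice(len(lineages), size=n, p=w)

    if config.mode == "MG":
        starts = rng.integers(0, L - rl + 1, size=n)
    else:
        weights = config.expression_weights
        if weights is None:
            weights = default_expression_weights(pair.annotations, read_length=rl)
        genes = {g.gene_id: g for g in pair.genes}
        unknown = set(weights) - set(genes)
        if unknown:
            raise SimulationError(f"expression_weights name unannotated genes: {sorted(unknown)}")
        short = [gid for gid in weights if genes[gid].length < rl]
        if short:
            warnings.warn(
                f"excluding {len(short)} gene(s) shorter than the read length "
                f"from expression_weights: {sorted(short)[:5]}...",
                stacklevel=2,
            )
        eligible = [(gid, weights[gid]) for gid in weights if genes[gid].length >= rl]
        if not eligible:
            raise SimulationError("no eligible genes left in expression_weights")
        gene_ids = [gid for gid, _ in eligible]
        gw = np.array([wt for _, wt in eligible], dtype=float)
        gw = gw / gw.sum()
        gene_starts = np.array([genes[g].start for g in gene_ids])
        gene_lens = np.array([genes[g].length for g in gene_ids])
        gene_idx = rng.choice(len(gene_ids), size=n, p=gw)
        offsets = rng.integers(0, gene_lens[gene_idx] - rl + 1)
        starts = gene_starts[gene_idx] + offsets

    window = starts[:, None] + np.arange(rl)[None, :]
    encoded = {lin: pair.encoded(lin) for lin in pair.lineages}
    slices = {lin: encoded[lin][window] for lin in pair.lineages}
    origin_names = [lineages[i] for i in origins]
    reads_arr = np.empty((n, rl), dtype=np.uint8)
    for i, lin in enumerate(lineages):
        sel = origins == i
        reads_arr[sel] = slices[lin][sel]

    err_mask = rng.random((n, rl)) < config.error_rate
    n_err_total = int(err_mask.sum())
    if n_err_total:
        shifts = rng.integers(1, 4, size=n_err_total).astype(np.uint8)
        reads_arr[err_mask] = (reads_arr[err_mask] + shifts) % 4
    n_errors = err_mask.sum(axis=1)

    mismatches = {lin: (reads_arr != slices[lin]).sum(axis=1) for lin in pair.lineages}

    prefix = config.read_id_prefix or config.mode
    reads: list[SequenceRecord] = []
    truth: list[TruthRecord] = []
    alignments: list[TabularAlignmentRecord] = []
    contig_of = {lin: pair.genomes[lin].id for lin in pair.lineages}
    for i in range(n):
        rid = f"{prefix}_{i:06d}"
        reads.append(SequenceRecord(id=rid, residues=_decode(reads_arr[i])))
        start = int(starts[i])
        truth.append(
            TruthRecord(
                read_id=rid,
                origin_lineage=origin_names[i],
                origin_start=start,
                origin_end=start + rl,
                n_errors=int(n_errors[i]),
            )
        )
        for lin in pair.lineages:
            mm = int(mismatches[lin][i])
            bits = _bitscore(rl - mm, mm)
            alignments.append(
                TabularAlignmentRecord(
                    qseqid=rid,
                    sseqid=contig_of[lin],
                    pident=100.0 * (1.0 - mm / rl),
                    length=rl,
                    mismatch=mm,
                    gapopen=0,
                    qstart=1,
                    qend=rl,
                    sstart=start + 1,
                    send=start + rl,
                    evalue=10.0 ** (-bits / 10.0) if bits < 200 else 1e-20,
                    bitscore=bits,
                    genome_id=lin,
                )
            )
    return ReadSet(config=config, reads=reads, truth=truth, truth_alignments=alignments)


# ---------------------------------------------------------------------------
# Codon pairs with known dN/dS
# ---------------------------------------------------------------------------

def simulate_codon_pair(config: CodonSimConfig) -> tuple[CodonPairAlignment, CodonSimTruth]:
    """Evolve one coding sequence away from a random ancestor at a known
    dN/dS ratio.

    Single-nucleotide codon changes are proposed uniformly; synonymous
    proposals are accepted with probability 1 and nonsynonymous with
    probability ``omega`` (for ``omega > 1`` the synonymous acceptance is
    scaled by ``1/omega`` instead).  Proposals creating stop codons are
    rejected.  Evolution stops once the number of accepted synonymous
    events reaches ``S_ancestor * expected_dS`` (NG86 synonymous sites of
    the ancestor), so the realised dS matches ``expected_dS`` up to
    sampling noise and multiple-hit correction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_codons
    anc = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n)]
    S_anc = sum(codon_sites(c)[0] for c in anc)
    target_syn = int(round(S_anc * config.expected_dS))

    if config.omega <= 1.0:
        acc_syn, acc_nonsyn = 1.0, config.omega
    else:
        acc_syn, acc_nonsyn = 1.0 / config.omega, 1.0

    max_proposals = config.max_proposals
    if max_proposals is None:
        max_proposals = max(200_000, 1_000 * max(target_syn, 1))

    seq2 = list(anc)
    syn_events = nonsyn_events = proposals = 0
    while syn_events < target_syn:
        proposals += 1
        if proposals > max_proposals:
            raise SimulationError(
                f"codon simulation did not reach expected_dS={config.expected_dS} "
                f"within {max_proposals} proposals"
            )
        ci = int(rng.integers(0, n))
        pos = int(rng.integers(0, 3))
        codon = seq2[ci]
        alts = BASES.replace(codon[pos], "")
        cand = codon[:pos] + alts[int(rng.integers(0, 3))] + codon[pos + 1 :]
        if cand in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[cand] == CODON_TO_AA[codon]
        acc = acc_syn if synonymous else acc_nonsyn
        if acc < 1.0 and rng.random() >= acc:
            continue
        seq2[ci] = cand
        if synonymous:
            syn_events += 1
        else:
            nonsyn_events += 1

    pair = CodonPairAlignment(
        gene_id=config.gene_id, seq1="".join(anc), seq2="".join(seq2)
    )
    return pair, CodonSimTruth(
        syn_events=syn_events,
        nonsyn_events=nonsyn_events,
        n_proposals=proposals,
        target_syn_events=target_syn,
        S_ancestor=S_anc,
    )
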