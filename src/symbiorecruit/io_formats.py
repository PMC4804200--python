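"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Everything held in memory is **0-based, half-open** ``[start, end)``.
Conversion to and from the 1-based inclusive conventions of GFF3 and
BLAST tabular output happens only at file boundaries.  Minus-strand
subject alignments (``sstart > send`` in outfmt-6) are normalised to
subject-forward intervals internally, with the strand retained as a flag.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "SequenceRecord",
    "AnnotationRecord",
    "TabularAlignmentRecord",
    "SampleMeta",
    "read_fasta",
    "write_fasta",
    "read_tabular_alignments",
    "write_tabular_alignments",
    "read_annotations",
    "write_annotations",
    "read_sample_table",
    "write_results",
    "TARA_TABLE1",
]

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = ("gene", "rRNA", "ITS")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """A file violated the declared format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has an empty sequence")
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise FormatError(
                f"sequence record {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnotationRecord:
    """A gene / rRNA / ITS feature, internal 0-based half-open coordinates."""

    seq_id: str
    feature_kind: str
    start: int
    end: int
    strand: str
    gene_id: str
    cluster_label: str | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise FormatError(
                f"feature kind {self.feature_kind!r} not one of {FEATURE_KINDS}"
            )
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TabularAlignmentRecord:
    """One read-vs-genome local alignment: the 12 standard outfmt-6 columns
    plus the genome the subject contig belongs to."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int  # 1-based inclusive query coordinates, qstart <= qend
    qend: int
    sstart: int  # 1-based inclusive subject coordinates; sstart > send on minus strand
    send: int
    evalue: float
    bitscore: float
    genome_id: str

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise FormatError(
                f"alignment {self.qseqid!r}: qstart {self.qstart} > qend {self.qend}"
            )
        if not (0.0 <= self.pident <= 100.0):
            raise FormatError(f"alignment {self.qseqid!r}: pident {self.pident} out of [0, 100]")
        if self.length < 1:
            raise FormatError(f"alignment {self.qseqid!r}: non-positive alignment length")
        if self.evalue < 0:
            raise FormatError(f"alignment {self.qseqid!r}: negative evalue")

    @property
    def strand(self) -> str:
        return "+" if self.sstart <= self.send else "-"

    @property
    def subject_start(self) -> int:
        """Subject-forward interval start, 0-based."""
        return min(self.sstart, self.send) - 1

    @property
    def subject_end(self) -> int:
        """Subject-forward interval end, half-open."""
        return max(self.sstart, self.send)

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart + 1


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: station, depth layer, size fraction, MG/MT."""

    sample: str
    station: str
    depth_layer: str  # SRF or DCM
    fraction: str  # e.g. "0.2-3", ">0.8"
    data_type: str  # MG or MT
    sequencing_depth: int

    def __post_init__(self) -> None:
        if self.depth_layer not in ("SRF", "DCM"):
            raise FormatError(f"sample {self.sample!r}: depth_layer must be SRF or DCM")
        if self.data_type not in ("MG", "MT"):
            raise FormatError(f"sample {self.sample!r}: data_type must be MG or MT")
        if self.sequencing_depth <= 0:
            raise FormatError(f"sample {self.sample!r}: sequencing_depth must be > 0")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, invalid: str = "error") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file.

    Residues are upper-cased.  ``invalid`` controls what happens to letters
    outside {A, C, G, T, N}: ``"error"`` rejects the file, ``"mask"`` maps
    them to N.
    """
    if invalid not in ("error", "mask"):
        raise ValueError(f"invalid= must be 'error' or 'mask', got {invalid!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed FASTA from Biopython's parser
        raise FormatError(f"{path}: {exc}") from exc
    if not parsed and path.stat().st_size > 0:
        raise FormatError(f"{path}: no FASTA records found (missing '>' header?)")
    for i, rec in enumerate(parsed, start=1):
        residues = str(rec.seq).upper()
        if not residues:
            raise FormatError(f"{path}: record {i} ({rec.id!r}) has an empty sequence")
        if invalid == "mask":
            residues = _NON_ACGTN.sub("N", residues)
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=residues, description=rec.description)
            )
        except FormatError as exc:
            raise FormatError(f"{path}: record {i}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BLAST outfmt-6 tabular alignments
# ---------------------------------------------------------------------------

_INT_COLS = (3, 4, 5, 6, 7, 8, 9)
_FLOAT_COLS = (2, 10, 11)


def read_tabular_alignments(
    path: str | Path, genome_id_map: Mapping[str, str]
) -> list[TabularAlignmentRecord]:
    """Read 12-column tab-separated alignments (BLAST ``-outfmt 6`` style).

    ``genome_id_map`` maps each subject id (contig) to the genome it belongs
    to; an unmapped subject id is an error.  Extra columns beyond 12 are
    ignored.
    """
    path = Path(path)
    out: list[TabularAlignmentRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                length, mismatch, gapopen, qstart, qend, sstart, send = (
                    int(cols[i]) for i in _INT_COLS
                )
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable numeric column: {exc}") from exc
            sseqid = cols[1]
            if sseqid not in genome_id_map:
                raise FormatError(
                    f"{path}:{lineno}: subject id {sseqid!r} missing from genome_id_map"
                )
            try:
                out.append(
                    TabularAlignmentRecord(
                        qseqid=cols[0],
                        sseqid=sseqid,
                        pident=pident,
                        length=length,
                        mismatch=mismatch,
                        gapopen=gapopen,
                        qstart=qstart,
                        qend=qend,
                        sstart=sstart,
                        send=send,
                        evalue=evalue,
                        bitscore=bitscore,
                        genome_id=genome_id_map[sseqid],
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_tabular_alignments(
    records: Iterable[TabularAlignmentRecord], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for r in records:
            handle.write(
                f"{r.qseqid}\t{r.sseqid}\t{r.pident:.2f}\t{r.length}\t{r.mismatch}\t"
                f"{r.gapopen}\t{r.qstart}\t{r.qend}\t{r.sstart}\t{r.send}\t"
                f"{r.evalue:.3g}\t{r.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Annotations: GFF3 (1-based inclusive on file) and BED (0-based half-open)
# ---------------------------------------------------------------------------

def _check_bounds(
    rec: AnnotationRecord, seq_lengths: Mapping[str, int] | None, where: str
) -> None:
    if seq_lengths is None:
        return
    if rec.seq_id in seq_lengths and rec.end > seq_lengths[rec.seq_id]:
        raise FormatError(
            f"{where}: feature {rec.gene_id!r} ends at {rec.end} beyond sequence "
            f"{rec.seq_id!r} length {seq_lengths[rec.seq_id]}"
        )


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_annotations(
    path: str | Path,
    dialect: str,
    *,
    seq_lengths: Mapping[str, int] | None = None,
    cluster_key: str = "cluster",
) -> list[AnnotationRecord]:
    """Read gene/rRNA/ITS annotations from GFF3 or BED.

    GFF3 rows with a feature type outside {gene, rRNA, ITS} are skipped.
    For BED, optional column 7 is the feature kind (default ``gene``) and
    column 8 the cluster label.  All coordinates are converted to the
    internal 0-based half-open convention.
    """
    dialect = dialect.lower()
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"dialect must be 'gff3' or 'bed', got {dialect!r}")
    path = Path(path)
    out: list[AnnotationRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            where = f"{path}:{lineno}"
            if dialect == "gff3":
                if len(cols) < 9:
                    raise FormatError(f"{where}: GFF3 requires 9 columns, got {len(cols)}")
                kind = cols[2]
                if kind not in FEATURE_KINDS:
                    continue
                try:
                    start1, end1 = int(cols[3]), int(cols[4])
                except ValueError as exc:
                    raise FormatError(f"{where}: unparsable coordinates: {exc}") from exc
                if start1 < 1 or end1 < start1:
                    raise FormatError(f"{where}: invalid GFF3 interval {start1}..{end1}")
                attrs = _parse_gff_attributes(cols[8])
                gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("locus_tag")
                if not gene_id:
                    raise FormatError(f"{where}: feature lacks an ID/gene_id attribute")
                rec = AnnotationRecord(
                    seq_id=cols[0],
                    feature_kind=kind,
                    start=start1 - 1,
                    end=end1,
                    strand=cols[6] if cols[6] in ("+", "-") else "+",
                    gene_id=gene_id,
                    cluster_label=attrs.get(cluster_key) or None,
                )
            else:  # BED
                if len(cols) < 4:
                    raise FormatError(f"{where}: BED requires >= 4 columns, got {len(cols)}")
                try:
                    start0, end0 = int(cols[1]), int(cols[2])
                except ValueError as exc:
                    raise FormatError(f"{where}: unparsable coordinates: {exc}") from exc
                if start0 < 0 or end0 <= start0:
                    raise FormatError(f"{where}: invalid BED interval {start0}..{end0}")
                kind = cols[6] if len(cols) > 6 and cols[6] else "gene"
                if kind not in FEATURE_KINDS:
                    raise FormatError(f"{where}: unknown feature kind {kind!r}")
                rec = AnnotationRecord(
                    seq_id=cols[0],
                    feature_kind=kind,
                    start=start0,
                    end=end0,
                    strand=cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "+",
                    gene_id=cols[3],
                    cluster_label=(cols[7] or None) if len(cols) > 7 else None,
                )
            _check_bounds(rec, seq_lengths, where)
            out.append(rec)
    _check_unique_gene_ids(out)
    return out


def _check_unique_gene_ids(records: Sequence[AnnotationRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if rec.feature_kind != "gene":
            continue
        key = (rec.seq_id, rec.gene_id)
        if key in seen:
            raise FormatError(
                f"duplicate gene id {rec.gene_id!r} on sequence {rec.seq_id!r}"
            )
        seen.add(key)


def write_annotations(
    records: Iterable[AnnotationRecord],
    path: str | Path,
    *,
    dialect: str = "gff3",
    cluster_key: str = "cluster",
) -> None:
    dialect = dialect.lower()
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"dialect must be 'gff3' or 'bed', got {dialect!r}")
    with open(path, "w") as handle:
        if dialect == "gff3":
            handle.write("##gff-version 3\n")
            for r in records:
                attrs = f"ID={r.gene_id}"
                if r.cluster_label:
                    attrs += f";{cluster_key}={r.cluster_label}"
                handle.write(
                    f"{r.seq_id}\tsymbiorecruit\t{r.feature_kind}\t{r.start + 1}\t{r.end}\t"
                    f".\t{r.strand}\t.\t{attrs}\n"
                )
        else:
            for r in records:
                cluster = r.cluster_label or ""
                handle.write(
                    f"{r.seq_id}\t{r.start}\t{r.end}\t{r.gene_id}\t.\t{r.strand}\t"
                    f"{r.feature_kind}\t{cluster}\n"
                )


# ---------------------------------------------------------------------------
# Sample metadata and result tables
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = ["sample", "station", "depth_layer", "fraction", "data_type", "sequencing_depth"]


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read a TSV of sample metadata (columns: sample, station, depth_layer,
    fraction, data_type, sequencing_depth)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing sample table columns {missing}")
    out = []
    for _, row in df.iterrows():
        try:
            depth = int(row["sequencing_depth"])
        except ValueError as exc:
            raise FormatError(
                f"{path}: sample {row['sample']!r}: bad sequencing_depth"
            ) from exc
        out.append(
            SampleMeta(
                sample=row["sample"],
                station=str(row["station"]),
                depth_layer=row["depth_layer"],
                fraction=row["fraction"],
                data_type=row["data_type"],
                sequencing_depth=depth,
            )
        )
    return out


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    float_precision: int = 6,
) -> list[dict]:
    """Write each DataFrame as ``<name>.tsv`` under ``out_dir``.

    Column order is taken from each frame as given; floats are written at a
    fixed precision so that re-running on the same inputs yields
    byte-identical files.  Returns a manifest: one ``{"file", "rows"}`` dict
    per table, in table order.
    """
    if not tables:
        raise ValueError("write_results: no tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, df in tables.items():
        fname = f"{name}.tsv"
        df.to_csv(
            out_dir / fname,
            sep="\t",
            index=False,
            float_format=f"%.{float_precision}f",
            lineterminator="\n",
        )
        manifest.append({"file": fname, "rows": int(len(df))})
    return manifest


# ---------------------------------------------------------------------------
# The printed sample table of the study (station, depth layer, data type,
# size fraction in um, total sequencing depth in reads, reads recruited per
# genome, and % genome recovery per genome).  Machine-readable form of the
# published per-sample metadata; used by examples as realistic input sizes.
# ---------------------------------------------------------------------------

TARA_TABLE1: pd.DataFrame = pd.DataFrame(
    [
        ("76", "SRF", "MG", "0.2-3", 177_019_968, 188_088, 26, 99.30, 0.14),
        ("76", "SRF", "MT", "0.2-3", 18_908_305, 25_340, 137, 21.35, 0.37),
        ("76", "SRF", "MG", ">0.8", 73_651_199, 54_776, 147, 98.61, 1.35),
        ("76", "SRF", "MT", ">0.8", 10_283_396, 12_143, 322, 15.01, 0.59),
        ("76", "DCM", "MG", ">0.8", 115_099_936, 848, 3, 9.00, 0.03),
        ("76", "DCM", "MT", ">0.8", 12_998_358, 76, 3, 0.49, 0.02),
        ("78", "SRF", "MG", "0.2-3", 155_580_203, 842_234, 2_395, 99.94, 13.95),
        ("78", "SRF", "MT", "0.2-3", 13_151_362, 133_693, 453, 46.61, 0.99),
        ("78", "SRF", "MG", "0.8-5", 105_731_269, 980_895, 24_021, 99.81, 90.24),
        ("78", "SRF", "MG", "5-20", 139_070_786, 1_182, 17_028, 10.14, 76.47),
        ("78", "SRF", "MT", "5-20", 97_646_287, 292, 17_862, 1.76, 34.69),
        ("78", "SRF", "MG", ">0.8", 163_575_710, 719_803, 81_528, 99.32, 99.03),
        ("78", "SRF", "MT", ">0.8", 9_966_043, 44_613, 9_415, 30.77, 11.51),
        ("78", "DCM", "MG", ">0.8", 86_446_300, 1_358, 45, 13.32, 0.48),
        ("78", "DCM", "MT", ">0.8", 10_659_304, 82, 10, 0.71, 0.07),
    ],
    columns=[
        "station",
        "depth_layer",
        "data_type",
        "fraction_um",
        "sequencing_depth",
        "fr_reads_A1",
        "fr_reads_A2",
        "recovery_pct_A1",
        "recovery_pct_A2",
    ],
)
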