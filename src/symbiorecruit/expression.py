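"""Whole-genome expression profiling from recruited metatranscriptome reads.

Per-gene transcript counting (reads above the population-identity
threshold overlapping the gene), the two normalisation schemes —
(i) per-cell: transcript counts divided by the mean count of single-copy
housekeeping genes (recA, gyrB), and (ii) metagenome-normalised:
depth-scaled MT/MG ratio per gene — plus gene-cluster aggregation
(relative contribution of each cluster to the total transcript pool) and
cross-sample linear regression of cluster abundances on the nitrogen
fixation operon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationRecord
from .recruitment import AssignedRead, FilterConfig

__all__ = [
    "GeneCountTable",
    "NormalizedExpression",
    "ClusterSummary",
    "RegressionResult",
    "count_transcripts_per_gene",
    "count_metagenome_per_gene",
    "build_count_table",
    "normalize_by_housekeeping",
    "normalize_by_metagenome",
    "aggregate_clusters",
    "regress_clusters",
    "cluster_map_from_annotations",
]

DEFAULT_HK_GENES = ("recA", "gyrB")
HK_METHODS = ("mean", "sum", "geometric")


@dataclass
class GeneCountTable:
    """Per-gene MT and MG read counts for one (sample pair, genome).

    Every annotated gene is present; genes without reads keep a zero.
    """

    frame: pd.DataFrame  # index: gene_id; columns: mt_count, mg_count

    def __post_init__(self) -> None:
        for col in ("mt_count", "mg_count"):
            if col not in self.frame.columns:
                raise ValueError(f"GeneCountTable requires column {col!r}")
            if (self.frame[col] < 0).any():
                raise ValueError("read counts cannot be negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)


@dataclass
class NormalizedExpression:
    """The two normalised forms; NaN marks values whose denominator was 0."""

    frame: pd.DataFrame  # index: gene_id; columns: per_cell, mg_norm
    hk_gene_ids: tuple[str, ...] = DEFAULT_HK_GENES
    hk_method: str = "mean"


@dataclass
class ClusterSummary:
    """Transcript counts per gene cluster and their relative contribution
    (percent of the genome's total MT count)."""

    frame: pd.DataFrame  # index: cluster; columns: transcript_count, relative_contribution_pct
    total_transcripts: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test on the slope, n - 2 df
    n: int


def _genes_only(annotations: Iterable[AnnotationRecord]) -> list[AnnotationRecord]:
    genes = [a for a in annotations if a.feature_kind == "gene"]
    if not genes:
        raise ValueError("no gene annotations supplied")
    return genes


def _count_reads(
    assigned: Sequence[AssignedRead],
    annotations: Iterable[AnnotationRecord],
    cfg: FilterConfig,
) -> pd.Series:
    """Count reads per gene: a read contributes to every gene whose interval
    it overlaps by >= 1 bp, provided its identity is strictly above the
    population threshold.  Genes with no reads keep 0; because one read can
    overlap several genes, the column sum may exceed the read count."""
    genes = sorted(_genes_only(annotations), key=lambda g: g.start)
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    counts = np.zeros(len(genes), dtype=int)
    for a in assigned:
        if a.ambiguous or a.record is None:
            continue
        if a.record.pident <= cfg.population_identity:
            continue
        s, e = a.record.subject_start, a.record.subject_end
        counts += (starts < e) & (ends > s)
    return pd.Series(counts, index=[g.gene_id for g in genes], name="count")


def count_transcripts_per_gene(
    assigned_mt: Sequence[AssignedRead],
    annotations: Iterable[AnnotationRecord],
    cfg: FilterConfig | None = None,
) -> pd.Series:
    """Metatranscript count per gene (reads already competitively assigned
    to this genome)."""
    return _count_reads(assigned_mt, annotations, cfg or FilterConfig()).rename("mt_count")


def count_metagenome_per_gene(
    assigned_mg: Sequence[AssignedRead],
    annotations: Iterable[AnnotationRecord],
    cfg: FilterConfig | None = None,
) -> pd.Series:
    """Metagenomic read count per gene — same counting contract as the
    transcript counter, applied to the paired MG sample."""
    return _count_reads(assigned_mg, annotations, cfg or FilterConfig()).rename("mg_count")


def build_count_table(mt_counts: pd.Series, mg_counts: pd.Series) -> GeneCountTable:
    if not mt_counts.index.equals(mg_counts.index):
        raise ValueError("MT and MG counts cover different gene sets")
    return GeneCountTable(
        frame=pd.DataFrame({"mt_count": mt_counts, "mg_count": mg_counts})
    )


def normalize_by_housekeeping(
    table: GeneCountTable,
    hk_gene_ids: Sequence[str] = DEFAULT_HK_GENES,
    method: str = "mean",
) -> pd.Series:
    """Per-cell expression: each gene's MT count divided by the combined MT
    count of the single-copy housekeeping genes.

    ``method`` combines the housekeeping counts by ``mean`` (default),
    ``sum`` or ``geometric`` mean.  A zero denominator flags every value
    missing (NaN) rather than raising.
    """
    if method not in HK_METHODS:
        raise ValueError(f"method must be one of {HK_METHODS}")
    missing = [g for g in hk_gene_ids if g not in table.frame.index]
    if missing:
        raise KeyError(f"housekeeping gene(s) absent from annotations: {missing}")
    hk = table.frame.loc[list(hk_gene_ids), "mt_count"].astype(float)
    if method == "mean":
        denom = hk.mean()
    elif method == "sum":
        denom = hk.sum()
    else:
        denom = float(stats.gmean(hk)) if (hk > 0).all() else 0.0
    mt = table.frame["mt_count"].astype(float)
    if denom == 0:
        return pd.Series(np.nan, index=mt.index, name="per_cell")
    return (mt / denom).rename("per_cell")


def normalize_by_metagenome(
    table: GeneCountTable, mt_depth: int, mg_depth: int
) -> pd.Series:
    """Depth-scaled MT/MG ratio per gene:
    (mt_count / mt_depth) / (mg_count / mg_depth).

    Genes with zero MG coverage are flagged missing (NaN); genes with zero
    MT count but observed MG coverage are 0.
    """
    if mt_depth <= 0 or mg_depth <= 0:
        raise ValueError("sequencing depths must be positive")
    mt = table.frame["mt_count"].astype(float)
    mg = table.frame["mg_count"].astype(float)
    out = (mt / mt_depth) / (mg / mg_depth).where(mg > 0)
    return out.rename("mg_norm")


def cluster_map_from_annotations(
    annotations: Iterable[AnnotationRecord],
) -> dict[str, str]:
    """gene_id -> cluster_label for every labelled gene."""
    return {
        a.gene_id: a.cluster_label
        for a in annotations
        if a.feature_kind == "gene" and a.cluster_label
    }


def aggregate_clusters(
    table: GeneCountTable,
    cluster_map: Mapping[str, str] | Iterable[tuple[str, str]],
) -> ClusterSummary:
    """Sum MT counts per cluster and express each cluster as a percentage of
    the genome's *total* MT count (so contributions over all clusters sum
    to <= 100)."""
    if isinstance(cluster_map, Mapping):
        pairs = list(cluster_map.items())
    else:
        pairs = list(cluster_map)
    seen: dict[str, str] = {}
    for gene, label in pairs:
        if gene in seen:
            raise ValueError(f"gene {gene!r} assigned to two clusters ({seen[gene]!r}, {label!r})")
        seen[gene] = label
    unknown = [g for g in seen if g not in table.frame.index]
    if unknown:
        raise KeyError(f"cluster map names genes absent from the count table: {unknown}")
    total = int(table.frame["mt_count"].sum())
    labels = sorted(set(seen.values()))
    rows = []
    for label in labels:
        genes = [g for g, lab in seen.items() if lab == label]
        count = int(table.frame.loc[genes, "mt_count"].sum())
        pct = 100.0 * count / total if total > 0 else 0.0
        rows.append(
            {"cluster": label, "transcript_count": count, "relative_contribution_pct": pct}
        )
    frame = pd.DataFrame(rows).set_index("cluster")
    return ClusterSummary(frame=frame, total_transcripts=total)


def regress_clusters(samples: Sequence[tuple[float, float]]) -> RegressionResult:
    """Ordinary least squares of another cluster's transcript counts on the
    nif-operon counts across samples; two-sided p from t = slope/se with
    n - 2 degrees of freedom."""
    if len(samples) < 3:
        raise ValueError(f"regression needs >= 3 samples, got {len(samples)}")
    x = np.array([s[0] for s in samples], dtype=float)
    y = np.array([s[1] for s in samples], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in nif-operon counts; regression undefined")
    if np.ptp(y) == 0:  # constant response: flat line, nothing explained
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=len(samples)
        )
    fit = stats.linregress(x, y)
    r_squared = float(fit.rvalue**2)
    p = float(fit.pvalue)
    if math.isnan(p):  # perfect fit: se == 0
        p = np.nextafter(0.0, 1.0)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        p_value=min(max(p, np.nextafter(0.0, 1.0)), 1.0),
        n=len(samples),
    )
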