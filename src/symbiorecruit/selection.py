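"""Nei–Gojobori (NG86) Ka/Ks estimation and the codon-based Z-test.

For each in-frame pair of coding sequences the module counts synonymous
and nonsynonymous *sites* (S, N) and *differences* (Sd, Nd), averaging
over substitution pathways for codons differing at more than one
position, applies the Jukes–Cantor correction to the proportions
pS = Sd/S and pN = Nd/N, and tests dS > dN (purifying selection) with a
Z statistic whose variance comes either from a codon-column bootstrap or
from a binomial/delta-method analytic formula.

Stop-codon policy
-----------------
Substitution pathways through stop codons are excluded from difference
counting (with uniform re-weighting of the surviving orderings).  For
*site* counting the default policy ``"excluded"`` likewise drops mutant
channels that create a stop codon from both S and N, so that the site
denominators describe exactly the substitutions the difference counter
(and any stop-avoiding evolutionary process) can realise.  The
alternative policy ``"nonsynonymous"`` counts stop channels as
nonsynonymous sites — the convention used by some NG86 implementations —
and is kept as a toggle; it slightly deflates dN.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import norm

from .io_formats import FormatError, SequenceRecord, read_fasta

__all__ = [
    "BASES",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CODON_TO_AA",
    "CodonPairAlignment",
    "KaKsResult",
    "ZTestResult",
    "SelectionSummary",
    "codon_sites",
    "count_differences",
    "jc_correct",
    "kaks",
    "z_test",
    "analyze_pair",
    "genome_summary",
    "read_codon_pairs",
    "write_codon_pairs",
    "results_to_frame",
]

BASES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_STOP_POLICIES = ("excluded", "nonsynonymous")

# lazily filled lookup tables, keyed by stop policy / codon pair
_SITES_CACHE: dict[str, dict[str, tuple[float, float]]] = {}
_DIFF_CACHE: dict[tuple[str, str], tuple[float, float, bool]] = {}


class SkipCodon(Exception):
    """Raised for codons that cannot be compared (stop / ambiguous / gapped)."""


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise SkipCodon(codon)
    if codon in STOP_CODONS:
        raise SkipCodon(codon)


def codon_sites(codon: str, *, stop_policy: str = "excluded") -> tuple[float, float]:
    """Return (synonymous, nonsynonymous) site counts for one sense codon.

    Each of the nine single-nucleotide mutant neighbours contributes 1/3 of
    a site to S or N according to whether it preserves the encoded amino
    acid.  Mutants that are stop codons follow ``stop_policy``.
    """
    if stop_policy not in _STOP_POLICIES:
        raise ValueError(f"stop_policy must be one of {_STOP_POLICIES}")
    _check_codon(codon)
    table = _SITES_CACHE.setdefault(stop_policy, {})
    if codon not in table:
        aa = CODON_TO_AA[codon]
        s = n = 0.0
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    if stop_policy == "nonsynonymous":
                        n += 1 / 3
                    continue
                if CODON_TO_AA[mutant] == aa:
                    s += 1 / 3
                else:
                    n += 1 / 3
        table[codon] = (s, n)
    return table[codon]


def count_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Return (synonymous, nonsynonymous) differences between two codons,
    averaged over all substitution orderings (NG86 pathway averaging).

    Orderings whose intermediate codons are stops are excluded and the
    remaining orderings re-weighted uniformly; in the (theoretical) case
    that every ordering is blocked, all orderings are used with steps into
    stop codons classified as nonsynonymous.
    """
    sd, nd, _ = _count_differences_full(codon1, codon2)
    return sd, nd


def _count_differences_full(codon1: str, codon2: str) -> tuple[float, float, bool]:
    _check_codon(codon1)
    _check_codon(codon2)
    key = (codon1, codon2)
    if key in _DIFF_CACHE:
        return _DIFF_CACHE[key]
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        result = (0.0, 0.0, False)
        _DIFF_CACHE[key] = result
        return result
    valid_paths: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        current = codon1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                nd += 1.0  # fallback classification only
            elif CODON_TO_AA.get(nxt, "*") == CODON_TO_AA.get(current, "*"):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        all_paths.append((sd, nd))
        if not blocked:
            valid_paths.append((sd, nd))
    fallback = not valid_paths
    paths = all_paths if fallback else valid_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    result = (sd, nd, fallback)
    _DIFF_CACHE[key] = result
    return result


def jc_correct(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3); NaN at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Pair-level estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonPairAlignment:
    """A pre-aligned, in-frame pair of coding sequences for one ortholog."""

    gene_id: str
    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise FormatError(
                f"pair {self.gene_id!r}: sequence lengths differ "
                f"({len(self.seq1)} vs {len(self.seq2)})"
            )
        if len(self.seq1) % 3 != 0:
            raise FormatError(
                f"pair {self.gene_id!r}: length {len(self.seq1)} not divisible by 3"
            )

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3


@dataclass
class ZTestResult:
    Z: float
    p_value: float
    var_dS: float
    var_dN: float
    variance_method: str
    alternative: str
    B: int | None = None
    seed: int | None = None
    degenerate: bool = False


@dataclass
class KaKsResult:
    """NG86 estimates for one ortholog pair (Z/P filled by :func:`z_test`)."""

    gene_id: str
    n_codons_compared: int
    n_codons_skipped: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    flags: tuple[str, ...] = ()
    Z: float = math.nan
    p_value: float = math.nan
    var_dS: float = math.nan
    var_dN: float = math.nan
    variance_method: str | None = None
    B: int | None = None
    seed: int | None = None
    # per compared codon: s1, n1, s2, n2, sd, nd — used by the bootstrap
    per_codon: np.ndarray | None = field(default=None, repr=False)


def _codon_components(
    pair: CodonPairAlignment, stop_policy: str
) -> tuple[np.ndarray, int, set[str]]:
    """Per-codon (s1, n1, s2, n2, sd, nd) for every comparable codon column."""
    rows: list[tuple[float, float, float, float, float, float]] = []
    skipped = 0
    flags: set[str] = set()
    for i in range(0, len(pair.seq1), 3):
        c1 = pair.seq1[i : i + 3].upper()
        c2 = pair.seq2[i : i + 3].upper()
        try:
            s1, n1 = codon_sites(c1, stop_policy=stop_policy)
            s2, n2 = codon_sites(c2, stop_policy=stop_policy)
            sd, nd, fallback = _count_differences_full(c1, c2)
        except SkipCodon:
            skipped += 1
            continue
        if fallback:
            flags.add("blocked_pathways")
        rows.append((s1, n1, s2, n2, sd, nd))
    return np.array(rows, dtype=float), skipped, flags


def kaks(
    pair: CodonPairAlignment, *, stop_policy: str = "excluded"
) -> KaKsResult:
    """NG86 point estimates (S, N, Sd, Nd, pS, pN, dS, dN, omega) for a pair.

    Codons containing gaps, ambiguous bases or stops in either sequence are
    skipped.  Saturation (p >= 3/4) and undefined omega (dS = 0 or NaN) are
    flagged rather than raised.
    """
    per_codon, skipped, flags = _codon_components(pair, stop_policy)
    if per_codon.size == 0:
        raise ValueError(f"pair {pair.gene_id!r}: no comparable codons")
    sums = per_codon.sum(axis=0)
    S = (sums[0] + sums[2]) / 2.0
    N = (sums[1] + sums[3]) / 2.0
    Sd, Nd = sums[4], sums[5]
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    dS = jc_correct(pS) if not math.isnan(pS) else math.nan
    dN = jc_correct(pN) if not math.isnan(pN) else math.nan
    if not math.isnan(pS) and pS >= 0.75:
        flags.add("saturated_dS")
    if not math.isnan(pN) and pN >= 0.75:
        flags.add("saturated_dN")
    if math.isnan(dS) or dS == 0.0:
        omega = math.nan
        flags.add("undefined_omega")
    elif math.isnan(dN):
        omega = math.nan
        flags.add("undefined_omega")
    else:
        omega = dN / dS
    return KaKsResult(
        gene_id=pair.gene_id,
        n_codons_compared=len(per_codon),
        n_codons_skipped=skipped,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        flags=tuple(sorted(flags)),
        per_codon=per_codon,
    )


def _jc_vec(p: np.ndarray) -> np.ndarray:
    d = np.full_like(p, np.nan)
    ok = p < 0.75
    d[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return d


def z_test(
    pair: CodonPairAlignment | KaKsResult,
    *,
    B: int = 1000,
    seed: int | None = None,
    alternative: str = "purifying",
    method: str = "bootstrap",
    stop_policy: str = "excluded",
) -> ZTestResult:
    """Codon-based Z-test of dS vs dN for one ortholog pair.

    ``Z = (dS - dN) / sqrt(var_dS + var_dN)``.  The default variance comes
    from resampling codon columns with replacement (``B`` replicates,
    seeded); ``method="analytic"`` instead propagates the binomial variance
    of pS and pN through the Jukes–Cantor correction (delta method).
    ``alternative``: ``"purifying"`` (one-tailed, dN < dS), ``"positive"``
    (one-tailed, dN > dS) or ``"two_sided"``.
    """
    if alternative not in ("purifying", "positive", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("bootstrap", "analytic"):
        raise ValueError(f"unknown variance method {method!r}")
    result = pair if isinstance(pair, KaKsResult) else kaks(pair, stop_policy=stop_policy)
    if result.per_codon is None:
        raise ValueError("KaKsResult lacks per-codon components; recompute with kaks()")
    dS, dN = result.dS, result.dN

    degenerate = False
    if math.isnan(dS) or math.isnan(dN):
        return ZTestResult(
            Z=math.nan, p_value=1.0, var_dS=math.nan, var_dN=math.nan,
            variance_method=method, alternative=alternative,
            B=B if method == "bootstrap" else None, seed=seed, degenerate=True,
        )

    if method == "bootstrap":
        per = result.per_codon
        k = len(per)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, k, size=(B, k))
        counts = np.zeros((B, k))
        for b in range(B):
            counts[b] = np.bincount(idx[b], minlength=k)
        sums = counts @ per  # (B, 6)
        S_b = (sums[:, 0] + sums[:, 2]) / 2.0
        N_b = (sums[:, 1] + sums[:, 3]) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            pS_b = np.where(S_b > 0, sums[:, 4] / S_b, np.nan)
            pN_b = np.where(N_b > 0, sums[:, 5] / N_b, np.nan)
        dS_b = _jc_vec(pS_b)
        dN_b = _jc_vec(pN_b)
        ok = ~(np.isnan(dS_b) | np.isnan(dN_b))
        if ok.sum() < 2:
            degenerate = True
            var_dS = var_dN = math.nan
        else:
            var_dS = float(np.var(dS_b[ok], ddof=1))
            var_dN = float(np.var(dN_b[ok], ddof=1))
    else:
        var_pS = result.pS * (1 - result.pS) / result.S
        var_pN = result.pN * (1 - result.pN) / result.N
        var_dS = var_pS / (1 - 4 * result.pS / 3) ** 2
        var_dN = var_pN / (1 - 4 * result.pN / 3) ** 2

    var_sum = (0.0 if degenerate else var_dS + var_dN)
    if degenerate or var_sum <= 0.0 or math.isnan(var_sum):
        return ZTestResult(
            Z=0.0, p_value=1.0, var_dS=var_dS, var_dN=var_dN,
            variance_method=method, alternative=alternative,
            B=B if method == "bootstrap" else None, seed=seed, degenerate=True,
        )
    Z = (dS - dN) / math.sqrt(var_sum)
    if alternative == "purifying":
        p = float(norm.sf(Z))
    elif alternative == "positive":
        p = float(norm.sf(-Z))
    else:
        p = float(2.0 * norm.sf(abs(Z)))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return ZTestResult(
        Z=float(Z), p_value=p, var_dS=var_dS, var_dN=var_dN,
        variance_method=method, alternative=alternative,
        B=B if method == "bootstrap" else None, seed=seed,
    )


def analyze_pair(
    pair: CodonPairAlignment,
    *,
    B: int = 1000,
    seed: int | None = None,
    alternative: str = "purifying",
    method: str = "bootstrap",
    stop_policy: str = "excluded",
) -> KaKsResult:
    """Run :func:`kaks` and :func:`z_test` and return the combined result."""
    result = kaks(pair, stop_policy=stop_policy)
    zt = z_test(result, B=B, seed=seed, alternative=alternative, method=method)
    result.Z = zt.Z
    result.p_value = zt.p_value
    result.var_dS = zt.var_dS
    result.var_dN = zt.var_dN
    result.variance_method = zt.variance_method
    result.B = zt.B
    result.seed = zt.seed
    if zt.degenerate:
        result.flags = tuple(sorted({*result.flags, "degenerate"}))
    return result


# ---------------------------------------------------------------------------
# Genome-wide summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSummary:
    n_genes: int
    n_purifying_significant: int
    n_positive_significant: int
    n_not_significant: int
    alpha: float

    def __post_init__(self) -> None:
        total = (
            self.n_purifying_significant
            + self.n_positive_significant
            + self.n_not_significant
        )
        if total != self.n_genes:
            raise ValueError("selection summary counts do not sum to n_genes")


def genome_summary(results: Sequence[KaKsResult], alpha: float = 0.05) -> SelectionSummary:
    """Count genes under significant purifying (p < alpha, dN < dS) or
    positive (p < alpha, dN > dS) selection.  No multiple-testing correction
    is applied."""
    purifying = positive = neither = 0
    for r in results:
        if (
            not math.isnan(r.p_value)
            and r.p_value < alpha
            and not math.isnan(r.dS)
            and not math.isnan(r.dN)
        ):
            if r.dN < r.dS:
                purifying += 1
                continue
            if r.dN > r.dS:
                positive += 1
                continue
        neither += 1
    return SelectionSummary(
        n_genes=len(results),
        n_purifying_significant=purifying,
        n_positive_significant=positive,
        n_not_significant=neither,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Paired-FASTA I/O (records "<gene>|1" and "<gene>|2") and result tables
# ---------------------------------------------------------------------------

def read_codon_pairs(path: str | Path) -> list[CodonPairAlignment]:
    records = read_fasta(path)
    by_gene: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in records:
        if "|" not in rec.id:
            raise FormatError(
                f"{path}: record {rec.id!r} does not follow the '<gene>|1' / '<gene>|2' convention"
            )
        gene, _, member = rec.id.rpartition("|")
        if member not in ("1", "2"):
            raise FormatError(f"{path}: record {rec.id!r}: member must be 1 or 2")
        if gene not in by_gene:
            by_gene[gene] = {}
            order.append(gene)
        if member in by_gene[gene]:
            raise FormatError(f"{path}: duplicate record {rec.id!r}")
        by_gene[gene][member] = rec.residues
    pairs = []
    for gene in order:
        members = by_gene[gene]
        if set(members) != {"1", "2"}:
            raise FormatError(f"{path}: gene {gene!r} lacks both members of the pair")
        pairs.append(CodonPairAlignment(gene_id=gene, seq1=members["1"], seq2=members["2"]))
    return pairs


def write_codon_pairs(pairs: Iterable[CodonPairAlignment], path: str | Path) -> None:
    from .io_formats import write_fasta

    records = []
    for p in pairs:
        records.append(SequenceRecord(id=f"{p.gene_id}|1", residues=p.seq1))
        records.append(SequenceRecord(id=f"{p.gene_id}|2", residues=p.seq2))
    write_fasta(records, path)


def results_to_frame(results: Sequence[KaKsResult]):
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "n_codons": r.n_codons_compared,
                "n_skipped": r.n_codons_skipped,
                "S": r.S,
                "N": r.N,
                "Sd": r.Sd,
                "Nd": r.Nd,
                "pS": r.pS,
                "pN": r.pN,
                "dS": r.dS,
                "dN": r.dN,
                "omega": r.omega,
                "Z": r.Z,
                "p_value": r.p_value,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
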