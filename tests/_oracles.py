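"""Independent brute-force oracles used by the test suite.

Deliberately written against different primitives than the package
(Biopython translation, per-position boolean masks, exhaustive
enumeration) so that agreement is a genuine cross-check rather than a
re-run of the implementation.
"""

from itertools import permutations

import numpy as np
from Bio.Seq import Seq


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_codon_sites(codon: str, stop_policy: str = "excluded"):
    """Enumerate all nine single-base mutants and classify each."""
    aa = _aa(codon)
    s = n = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            maa = _aa(mutant)
            if maa == "*":
                if stop_policy == "nonsynonymous":
                    n += 1 / 3
                continue
            if maa == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def brute_count_differences(c1: str, c2: str):
    """Average (syn, nonsyn) steps over substitution orderings, excluding
    orderings that pass through a stop codon (uniform fallback if all do)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    clean, every = [], []
    for order in permutations(positions):
        current = c1
        sd = nd = 0.0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if _aa(nxt) == "*":
                hit_stop = True
                nd += 1
            elif _aa(nxt) == _aa(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        every.append((sd, nd))
        if not hit_stop:
            clean.append((sd, nd))
    use = clean or every
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


def brute_recruitment(records, read_lengths, masks, genome_lengths, cfg):
    """Filter + assign + recover with per-position sets and boolean masks.

    Returns (retained ids as a set of (qseqid, genome_id), assignment dict
    read -> genome or None for ambiguous, covered positions per genome).
    """
    masked = {g: set() for g in genome_lengths}
    for g, intervals in masks.items():
        for s, e in intervals:
            masked[g].update(range(s, e))

    retained = []
    for r in records:
        rl = read_lengths[r.qseqid]
        lo = min(r.sstart, r.send) - 1
        hi = max(r.sstart, r.send)
        if (
            r.pident >= cfg.min_pident
            and r.evalue <= cfg.max_evalue
            and (r.qend - r.qstart + 1) / rl >= cfg.min_query_coverage
            and not (set(range(lo, hi)) & masked.get(r.genome_id, set()))
        ):
            retained.append(r)

    by_read = {}
    for r in retained:
        by_read.setdefault(r.qseqid, []).append(r)
    assignment = {}
    assigned_records = {}
    for read_id, hits in by_read.items():
        best = max((h.bitscore, h.pident) for h in hits)
        top = [h for h in hits if (h.bitscore, h.pident) == best]
        genomes = {h.genome_id for h in top}
        if len(genomes) == 1:
            assignment[read_id] = top[0].genome_id
            assigned_records[read_id] = top[0]
        else:
            assignment[read_id] = None

    covered = {}
    for g, L in genome_lengths.items():
        mask = np.zeros(L, dtype=bool)
        for read_id, genome in assignment.items():
            if genome != g:
                continue
            r = assigned_records[read_id]
            if r.pident > cfg.population_identity:
                mask[min(r.sstart, r.send) - 1 : max(r.sstart, r.send)] = True
        covered[g] = int(mask.sum())

    retained_ids = {(r.qseqid, r.genome_id) for r in retained}
    return retained_ids, assignment, covered
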