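"""Read-backed linkage between variant pairs and paralog best-match checks.

Linkage evidence is strictly single-read co-occurrence: no statistical
phasing is attempted across pairs that no read spans. Paralog comparison is
gap-free (copies are generated without indels), matching reads to candidate
gene copies at identical within-gene offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pileup import VariantCall
from .simulate import (AlignedRead, GeneModel, ReadSet, ReferenceGenome,
                       _CODE, BASES, encode_seq)

VariantKey = tuple  # (position, ref, alt)


@dataclass
class LinkageRecord:
    """Co-occurrence tally for one variant pair over the reads spanning both."""

    variant_a: VariantKey
    variant_b: VariantKey
    reads_spanning_both: int
    reads_with_both_alts: int
    reads_with_exactly_one_alt: int

    def __post_init__(self):
        neither = (self.reads_spanning_both - self.reads_with_both_alts
                   - self.reads_with_exactly_one_alt)
        if neither < 0:
            raise ValueError("inconsistent linkage tallies")

    @property
    def linkage_fraction(self) -> float:
        """Both-alt reads over all spanning reads; NaN when nothing spans."""
        if self.reads_spanning_both == 0:
            return math.nan
        return self.reads_with_both_alts / self.reads_spanning_both


def _as_readset(reads) -> ReadSet:
    return reads if isinstance(reads, ReadSet) else ReadSet.from_reads(list(reads))


def pairwise_linkage(reads, variant_pairs) -> list[LinkageRecord]:
    """Tally alt co-occurrence for each variant pair over spanning reads.

    Pairs farther apart than the read length simply produce a record with
    zero spanning reads. Deterministic.
    """
    rs = _as_readset(reads)
    records = []
    for a, b in variant_pairs:
        lo, hi = min(a[0], b[0]), max(a[0], b[0])
        span = rs.spanning(lo, hi)
        if span.size == 0:
            records.append(LinkageRecord(a, b, 0, 0, 0))
            continue
        alt_a = rs.base_at(span, a[0]) == _CODE[a[2]]
        alt_b = rs.base_at(span, b[0]) == _CODE[b[2]]
        both = int(np.sum(alt_a & alt_b))
        one = int(np.sum(alt_a ^ alt_b))
        records.append(LinkageRecord(a, b, int(span.size), both, one))
    return records


def linked_groups(records: list[LinkageRecord], min_fraction: float = 0.9,
                  min_spanning: int = 10) -> list[frozenset]:
    """Single-linkage clustering over well-supported high-linkage pairs.

    An edge joins a pair with linkage_fraction >= min_fraction and
    reads_spanning_both >= min_spanning; groups are the connected
    components (variants in no qualifying pair stay singletons).
    """
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for r in records:
        find(r.variant_a)
        find(r.variant_b)
        if (r.reads_spanning_both >= min_spanning
                and r.linkage_fraction >= min_fraction):
            union(r.variant_a, r.variant_b)

    groups: dict = {}
    for v in parent:
        groups.setdefault(find(v), set()).add(v)
    return sorted((frozenset(g) for g in groups.values()),
                  key=lambda g: sorted(g))


@dataclass
class ParalogAssignment:
    """Best-matching paralogous gene copy for one read."""

    read_id: str
    candidate_gene_ids: list
    mismatches_per_candidate: list
    assigned_gene_id: str   # gene_id or "AMBIGUOUS"


def paralog_best_match(read: AlignedRead, candidates: list[GeneModel],
                       genome: ReferenceGenome) -> ParalogAssignment:
    """Compare a read against each paralogous copy at matched within-gene
    offsets and assign the unique minimum-mismatch copy (tie -> AMBIGUOUS).

    The read must overlap at least one candidate span; the overlap window
    relative to that copy is transplanted onto every other copy gap-free.
    """
    codes = encode_seq(read.sequence)
    home = None
    for g in candidates:
        if read.start < g.end and read.start + len(codes) > g.start:
            home = g
            break
    if home is None:
        raise ValueError(
            f"read {read.read_id} overlaps no candidate paralog copy")

    lo = max(read.start, home.start)
    hi = min(read.start + len(codes), home.end)
    read_win = codes[lo - read.start:hi - read.start]
    off_lo, off_hi = lo - home.start, hi - home.start

    mismatches = []
    for g in candidates:
        if off_hi > g.length:
            mismatches.append(len(read_win))  # window missing: all mismatch
            continue
        gene_win = genome.codes[g.start + off_lo:g.start + off_hi]
        mismatches.append(int(np.sum(read_win != gene_win)))

    best = min(mismatches)
    winners = [g.gene_id for g, m in zip(candidates, mismatches) if m == best]
    assigned = winners[0] if len(winners) == 1 else "AMBIGUOUS"
    return ParalogAssignment(
        read_id=read.read_id,
        candidate_gene_ids=[g.gene_id for g in candidates],
        mismatches_per_candidate=mismatches,
        assigned_gene_id=assigned)


def assign_paralog_reads(reads, group: list[GeneModel],
                         genome: ReferenceGenome) -> list[ParalogAssignment]:
    """Run the best-match check for every read overlapping any copy in a
    paralog group."""
    out = []
    for r in (reads if not isinstance(reads, ReadSet) else iter(reads)):
        if any(r.start < g.end and r.start + len(r.sequence) > g.start
               for g in group):
            out.append(paralog_best_match(r, group, genome))
    return out
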