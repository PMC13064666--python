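"""Per-position allele counts, pool-aware variant calling, and coding-effect
annotation.

The caller is deliberately simple: pooled-isolate sequencing turns variant
calling into frequency estimation, so a call is any (position, non-reference
base) whose read support clears the detection rule, with frequency exactly
alt_count / depth. Only substitutions are handled; reads are ungapped and
match-only by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import Seq

from .config import DetectionRule
from .simulate import (AlignedRead, GeneModel, ReadSet, ReferenceGenome,
                       BASES, _CODE, encode_seq)

logger = logging.getLogger(__name__)


@dataclass
class PileupColumn:
    position: int
    counts: dict            # base -> read count
    depth: int

    def __post_init__(self):
        if self.depth != sum(self.counts.values()):
            raise ValueError("depth must equal the sum of base counts")


class Pileup:
    """Dense per-position base counts over one reference genome."""

    def __init__(self, genome: ReferenceGenome, counts: np.ndarray):
        if counts.shape != (4, len(genome)):
            raise ValueError("counts must be 4 x genome_length")
        self.genome = genome
        self.counts = counts
        self.depth = counts.sum(axis=0)

    def column(self, position: int) -> PileupColumn:
        c = {BASES[b]: int(self.counts[b, position]) for b in range(4)
             if self.counts[b, position] > 0}
        return PileupColumn(position=position, counts=c,
                            depth=int(self.depth[position]))

    def columns(self):
        """Covered positions only, in coordinate order."""
        for pos in np.nonzero(self.depth > 0)[0]:
            yield self.column(int(pos))


def _pileup_from_readset(reads: ReadSet, genome: ReferenceGenome) -> np.ndarray:
    L, rl = len(genome), reads.read_length
    starts = reads.starts
    if len(starts) and (starts.min() < 0 or starts.max() + rl > L):
        raise ValueError("read exceeds genome bounds")
    counts = np.zeros((4, L), dtype=np.int64)

    events = np.zeros(L + 1, dtype=np.int64)
    np.add.at(events, starts, 1)
    np.add.at(events, starts + rl, -1)
    coverage = np.cumsum(events[:-1])

    offsets = np.arange(rl)
    ref_win = genome.codes[starts[:, None] + offsets]
    mm = reads.seqs != ref_win
    mm_rows, mm_cols = np.nonzero(mm)
    mm_pos = starts[mm_rows] + mm_cols
    mm_base = reads.seqs[mm_rows, mm_cols]
    for b in range(4):
        sel = mm_pos[mm_base == b]
        if sel.size:
            counts[b] += np.bincount(sel, minlength=L)
    n_mm = np.bincount(mm_pos, minlength=L) if mm_pos.size else np.zeros(L, int)
    ref_counts = coverage - n_mm
    counts[genome.codes, np.arange(L)] += ref_counts
    return counts


def _pileup_from_reads(reads, genome: ReferenceGenome) -> np.ndarray:
    L = len(genome)
    counts = np.zeros((4, L), dtype=np.int64)
    for r in reads:
        codes = encode_seq(r.sequence)
        if r.start < 0 or r.start + len(codes) > L:
            raise ValueError(f"read {r.read_id} exceeds genome bounds")
        pos = np.arange(r.start, r.start + len(codes))
        np.add.at(counts, (codes, pos), 1)
    return counts


def build_pileup(reads, genome: ReferenceGenome) -> Pileup:
    """Accumulate per-position base counts from pre-aligned, match-only reads.

    Accepts a :class:`ReadSet` (vectorized path) or any iterable of
    :class:`AlignedRead` (generic path, variable read lengths allowed).
    """
    if isinstance(reads, ReadSet):
        counts = _pileup_from_readset(reads, genome)
    else:
        counts = _pileup_from_reads(reads, genome)
    return Pileup(genome, counts)


@dataclass
class VariantCall:
    """One substitution call with its pool-level frequency estimate."""

    position: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    frequency: float
    gene_id: str | None = None
    effect: str | None = None       # synonymous | non-synonymous | intergenic
    codon_change: str | None = None
    aa_change: str | None = None

    def __post_init__(self):
        if self.alt_base == self.ref_base:
            raise ValueError("alt base equals reference base")
        if self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency outside [0, 1]")

    @property
    def key(self):
        return (self.position, self.ref_base, self.alt_base)


def call_variants(pileup: Pileup, genome: ReferenceGenome,
                  rule: DetectionRule | None = None) -> list[VariantCall]:
    """One call per (position, non-reference base) clearing the rule.

    Multi-allelic positions yield one call per alt base; frequency is
    alt_count / depth exactly. Deterministic given the pileup and rule.
    """
    rule = rule or DetectionRule()
    counts, depth = pileup.counts, pileup.depth
    L = len(genome)
    ref = genome.codes
    calls = []
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, counts / np.maximum(depth, 1), 0.0)
    for b in range(4):
        mask = ((ref != b) & (counts[b] >= rule.min_alt_reads)
                & (freq[b] >= rule.min_frequency) & (depth > 0))
        for pos in np.nonzero(mask)[0]:
            calls.append(VariantCall(
                position=int(pos), ref_base=BASES[ref[pos]], alt_base=BASES[b],
                alt_count=int(counts[b, pos]), depth=int(depth[pos]),
                frequency=float(counts[b, pos] / depth[pos])))
    calls.sort(key=lambda c: (c.position, c.alt_base))
    return calls


# ---------------------------------------------------------------------------
# coding-effect annotation
# ---------------------------------------------------------------------------

def _find_gene(position: int, genes: list[GeneModel]) -> GeneModel | None:
    for g in genes:
        if g.contains(position):
            return g
    return None


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def annotate_effect(call: VariantCall, genes: list[GeneModel],
                    genome: ReferenceGenome) -> VariantCall:
    """Classify a substitution as synonymous / non-synonymous / intergenic.

    The strand-aware codon containing the position is translated with the
    standard genetic code before and after the substitution; stop-codon
    gains count as non-synonymous (the census uses a binary split). Genes
    whose length is not divisible by 3 are logged and treated as
    non-annotatable (the call falls back to intergenic).
    """
    gene = _find_gene(call.position, genes)
    if gene is None:
        return replace(call, gene_id=None, effect="intergenic")
    if gene.length % 3:
        logger.warning("gene %s length %d not divisible by 3; "
                       "call at %d left unannotated",
                       gene.gene_id, gene.length, call.position)
        return replace(call, gene_id=None, effect="intergenic")

    gene_seq = genome.sequence[gene.start:gene.end]
    if gene.strand == "+":
        pos_in_gene = call.position - gene.start
        ref_b, alt_b = call.ref_base, call.alt_base
    else:
        gene_seq = _revcomp(gene_seq)
        pos_in_gene = gene.end - 1 - call.position
        ref_b = call.ref_base.translate(_REV)
        alt_b = call.alt_base.translate(_REV)

    ci = pos_in_gene // 3
    off = pos_in_gene % 3
    codon = gene_seq[3 * ci:3 * ci + 3]
    if codon[off] != ref_b:
        raise ValueError(
            f"reference base mismatch at {call.position} in {gene.gene_id}")
    alt_codon = codon[:off] + alt_b + codon[off + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    effect = "synonymous" if aa_ref == aa_alt else "non-synonymous"
    return replace(call, gene_id=gene.gene_id, effect=effect,
                   codon_change=f"{codon}>{alt_codon}",
                   aa_change=f"{aa_ref}{ci + 1}{aa_alt}")


_REV = str.maketrans("ACGT", "TGCA")


def annotate_all(calls: list[VariantCall], genes: list[GeneModel],
                 genome: ReferenceGenome) -> list[VariantCall]:
    return [annotate_effect(c, genes, genome) for c in calls]
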