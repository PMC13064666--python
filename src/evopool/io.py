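"""Format readers/writers shared by every stage.

Internal coordinates are 0-based half-open everywhere; the conversion to the
1-based conventions of GFF3, SAM and VCF happens exactly once, here, at the
file boundary. Every file written carries a header comment with the tool
version, the config hash and the seed, so a results directory is
self-describing. Readers go through the established parsers (Biopython,
pysam, gffutils); writers emit the narrow subset of each format the pipeline
produces (match-only CIGARs, substitution-only VCF records).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .pileup import VariantCall
from .simulate import AlignedRead, GeneModel, ReadSet, ReferenceGenome


def stamp(seed=None, config_hash=None) -> str:
    parts = [f"evopool={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fasta(genome: ReferenceGenome, path, seed=None, config_hash=None):
    rec = SeqRecord(Seq(genome.sequence), id=genome.genome_id,
                    description=f"topology={genome.topology} "
                                f"{stamp(seed, config_hash)}")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> ReferenceGenome:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"{path}: no FASTA records")
    topology = "linear"
    for field in recs[0].description.split():
        if field.startswith("topology="):
            topology = field.split("=", 1)[1]
    return ReferenceGenome(genome_id=recs[0].id, sequence=str(recs[0].seq),
                           topology=topology)


def write_fastq(reads, path, seed=None, config_hash=None):
    """Reads with constant quality; descriptions carry the truth lineage and
    the run stamp (FASTQ has no comment lines of its own)."""
    tag = stamp(seed, config_hash)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} lineage={r.true_lineage} {tag}\n"
                     f"{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path) -> list[tuple]:
    """(read_id, sequence, description) tuples; FASTQ carries no coordinates."""
    return [(rec.id, str(rec.seq), rec.description)
            for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# SAM subset
# ---------------------------------------------------------------------------

def write_sam(reads, genome: ReferenceGenome, path,
              seed=None, config_hash=None):
    """Mandatory-column SAM with match-only CIGARs and truth-lineage tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.genome_id, "LN": len(genome)}],
        "PG": [{"ID": "evopool", "PN": "evopool", "VN": __version__}],
        "CO": [stamp(seed, config_hash)],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = r.start
            seg.mapping_quality = 60
            seg.cigartuples = [(0, len(r.sequence))]
            seg.query_sequence = r.sequence
            if r.true_lineage is not None:
                seg.set_tag("ln", r.true_lineage, "Z")
            if r.sample_id:
                seg.set_tag("sm", r.sample_id, "Z")
            out.write(seg)


def read_sam(path):
    """Parse a SAM-subset file back into reads.

    Returns a :class:`ReadSet` when all reads share one length, else a list
    of :class:`AlignedRead`. Any CIGAR operation other than a single match
    run is rejected explicitly.
    """
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
        genome_id = fh.references[0] if fh.nreferences else ""
        for i, seg in enumerate(fh.fetch(until_eof=True)):
            if seg.is_unmapped:
                continue
            ct = seg.cigartuples or []
            if len(ct) != 1 or ct[0][0] != 0:
                raise ValueError(
                    f"{path} line {i + 1}: unsupported CIGAR "
                    f"{seg.cigarstring!r}; only <len>M is supported")
            reads.append(AlignedRead(
                read_id=seg.query_name,
                genome_id=seg.reference_name or genome_id,
                start=seg.reference_start,
                sequence=seg.query_sequence,
                sample_id=seg.get_tag("sm") if seg.has_tag("sm") else "",
                true_lineage=seg.get_tag("ln") if seg.has_tag("ln") else None,
            ))
    if reads and len({len(r.sequence) for r in reads}) == 1:
        return ReadSet.from_reads(reads)
    return reads


# ---------------------------------------------------------------------------
# VCF v4.2 subset
# ---------------------------------------------------------------------------

def _vcf_header(genome: ReferenceGenome, info_lines, seed, config_hash):
    lines = ["##fileformat=VCFv4.2",
             f"##source=evopool {__version__}",
             f"##evopool={stamp(seed, config_hash)}",
             f"##contig=<ID={genome.genome_id},length={len(genome)}>"]
    lines += info_lines
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


_CALL_INFO = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">',
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt read count">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">',
]
_TRUTH_INFO = [
    '##INFO=<ID=TRUEAF,Number=A,Type=Float,Description="Truth allele frequency">',
]


def write_vcf(calls: list[VariantCall], genome: ReferenceGenome, path,
              seed=None, config_hash=None):
    with open(path, "w") as fh:
        fh.write(_vcf_header(genome, _CALL_INFO, seed, config_hash))
        for c in sorted(calls, key=lambda c: (c.position, c.alt_base)):
            info = [f"AF={c.frequency:.6g}", f"AC={c.alt_count}",
                    f"DP={c.depth}"]
            if c.effect:
                info.append(f"EFF={c.effect}")
            if c.gene_id:
                info.append(f"GENE={c.gene_id}")
            fh.write(f"{genome.genome_id}\t{c.position + 1}\t.\t{c.ref_base}"
                     f"\t{c.alt_base}\t.\tPASS\t{';'.join(info)}\n")


def read_vcf(path) -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            for alt in rec.alts or ():
                af = rec.info.get("AF")
                ac = rec.info.get("AC")
                dp = int(rec.info.get("DP", 0))
                af = float(af[0] if isinstance(af, tuple) else af)
                if ac is not None:
                    ac = int(ac[0] if isinstance(ac, tuple) else ac)
                else:
                    ac = int(round(af * dp))
                calls.append(VariantCall(
                    position=rec.pos - 1, ref_base=rec.ref, alt_base=alt,
                    alt_count=ac, depth=dp, frequency=ac / dp if dp else af,
                    gene_id=rec.info.get("GENE"),
                    effect=rec.info.get("EFF")))
    return calls


def write_truth_vcf(mutations, af_by_mutation: dict,
                    genome: ReferenceGenome, path,
                    seed=None, config_hash=None):
    """Truth mutations with their population frequencies (INFO key TRUEAF)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(genome, _TRUTH_INFO, seed, config_hash))
        for pos, ref, alt in sorted(mutations):
            af = af_by_mutation.get((pos, ref, alt), 0.0)
            fh.write(f"{genome.genome_id}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t"
                     f"PASS\tTRUEAF={af:.6g}\n")


def read_truth_vcf(path) -> dict:
    """{(position, ref, alt): true allele frequency}."""
    out = {}
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            for alt in rec.alts or ():
                af = rec.info.get("TRUEAF", 0.0)
                af = float(af[0] if isinstance(af, tuple) else af)
                out[(rec.pos - 1, rec.ref, alt)] = af
    return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], genome: ReferenceGenome, path,
               seed=None, config_hash=None):
    """Gene models, converted to GFF3's 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#!{stamp(seed, config_hash)}\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome)}\n")
        for g in sorted(genes, key=lambda g: g.start):
            attrs = [f"ID={g.gene_id}", f"Name={g.gene_id}",
                     f"product={g.annotation}",
                     f"selection_class={g.selection_class}"]
            if g.paralog_group:
                attrs.append(f"paralog_group={g.paralog_group}")
            fh.write(f"{genome.genome_id}\tevopool\tgene\t{g.start + 1}\t"
                     f"{g.end}\t.\t{g.strand}\t0\t{';'.join(attrs)}\n")


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True)
    genes = []
    for f in db.features_of_type("gene", order_by="start"):
        attr = {k: v[0] for k, v in f.attributes.items() if v}
        genes.append(GeneModel(
            gene_id=attr.get("ID", f.id),
            start=f.start - 1, end=f.end,
            strand=f.strand if f.strand in "+-" else "+",
            annotation=attr.get("product", ""),
            paralog_group=attr.get("paralog_group"),
            selection_class=attr.get("selection_class", "neutral")))
    return genes


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, seed=None, config_hash=None,
              index: bool = True):
    """TSV with '#'-prefixed stamp header lines."""
    with open(path, "w") as fh:
        fh.write(f"# {stamp(seed, config_hash)}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
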