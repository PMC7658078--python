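"""File formats: FASTA/FASTQ, BED-like TSVs, GFF3, alignment-block TSV.

Coordinates are stored 0-based half-open in all BED-like files (BED
convention); GFF3 is written/read 1-based inclusive (GFF convention).
"""

from __future__ import annotations

import csv
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

from .detect import AlignmentBlock, MICall
from .intervals import GenomicInterval
from .regions import MIR, AnnotationIndex, Gene
from .simulate import ReferenceGenome, SimRead, SimTruth


# -- reference & reads -------------------------------------------------------


def write_reference_fasta(ref: ReferenceGenome, path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in ref.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path) -> ReferenceGenome:
    return ReferenceGenome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_reads_fastq(reads: Sequence[SimRead], path) -> None:
    """FASTQ with constant quality 'I' (Phred 40)."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_reads_fasta(reads: Sequence[SimRead], path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.name, description="") for r in reads]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ reads as (name, sequence) pairs."""
    path = str(path)
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, fmt)]


# -- truth / population map --------------------------------------------------


def write_truth_bed(truth: SimTruth, path) -> None:
    """Planted alleles as BED6 (name=allele id, score=0, strand '+')."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a in truth.alleles:
            iv = a.interval
            w.writerow([iv.chromosome, iv.start, iv.end, a.allele_id, 0, "+"])


def write_genotypes_tsv(truth: SimTruth, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["individual", "allele_id"])
        for ind in sorted(truth.genotypes):
            for aid in sorted(truth.genotypes[ind]):
                w.writerow([ind, aid])


def write_population_map_tsv(population_map: Mapping[str, tuple[str, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["individual", "population", "super_population"])
        for ind in sorted(population_map):
            pop, sup = population_map[ind]
            w.writerow([ind, pop, sup])


def read_population_map_tsv(path) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["individual"]] = (row["population"], row["super_population"])
    return out


# -- MI calls & MIRs ---------------------------------------------------------

_CALL_HEADER = [
    "chrom", "start", "end", "name", "score", "strand",
    "individual", "population", "ref_allele_seq", "inv_allele_seq",
]


def write_calls_tsv(calls: Sequence[MICall], path) -> None:
    """MI calls as BED6+4 (score = read support)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CALL_HEADER)
        for i, c in enumerate(calls, start=1):
            iv = c.interval
            w.writerow([
                iv.chromosome, iv.start, iv.end, f"MI{i:05d}", c.support, "+",
                c.individual, c.population,
                c.reference_allele_sequence, c.inverted_allele_sequence,
            ])


def read_calls_tsv(path) -> list[MICall]:
    calls = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            calls.append(
                MICall(
                    interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    individual=row["individual"],
                    population=row["population"],
                    reference_allele_sequence=row["ref_allele_seq"],
                    inverted_allele_sequence=row["inv_allele_seq"],
                    support=int(row["score"]),
                )
            )
    return calls


def write_mirs_tsv(mirs: Sequence[MIR], path, classes: Mapping[str, str] | None = None) -> None:
    """MIRs as BED6+2 (score = hits, then region class and member ids)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "name", "hits", "strand", "region_class", "members"])
        for m in mirs:
            iv = m.interval
            members = ",".join(f"{c.individual}@{c.interval.start}-{c.interval.end}" for c in m.members)
            cls = classes.get(m.mir_id, ".") if classes else "."
            w.writerow([iv.chromosome, iv.start, iv.end, m.mir_id, m.hits, "+", cls, members])


# -- alignment blocks --------------------------------------------------------


def write_alignment_blocks_tsv(blocks: Sequence[AlignmentBlock], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "ref_start", "ref_seq", "query_seq"])
        for b in blocks:
            w.writerow([b.chromosome, b.ref_start, b.ref_seq, b.query_seq])


def read_alignment_blocks_tsv(path) -> list[AlignmentBlock]:
    blocks = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            blocks.append(
                AlignmentBlock(row["chrom"], int(row["ref_start"]), row["ref_seq"], row["query_seq"])
            )
    return blocks


# -- GFF3 --------------------------------------------------------------------


def write_gff3(ann: AnnotationIndex, path) -> None:
    """Write the annotation as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            def line(ftype: str, s: int, e: int, fid: str, parent: str | None) -> str:
                attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
                attrs += f";gene_type={g.biotype}"
                return "\t".join(
                    [g.chromosome, "microinv", ftype, str(s + 1), str(e), ".", g.strand, ".", attrs]
                ) + "\n"

            fh.write(line("gene", g.start, g.end, g.gene_id, None))
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(line("exon", s, e, f"{g.gene_id}.exon{i}", g.gene_id))
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(line("CDS", s, e, f"{g.gene_id}.cds{i}", g.gene_id))
            for i, (s, e) in enumerate(g.utrs, 1):
                fh.write(line("UTR", s, e, f"{g.gene_id}.utr{i}", g.gene_id))
            for i, (s, e) in enumerate(g.other_features, 1):
                fh.write(line("miRNA", s, e, f"{g.gene_id}.other{i}", g.gene_id))


_UTR_TYPES = {"UTR", "five_prime_UTR", "three_prime_UTR", "5UTR", "3UTR"}
_OTHER_EXONIC_TYPES = {"miRNA", "mt_rRNA", "rRNA", "snoRNA", "ncRNA"}


def read_gff3(path, promoter_length: int = 2000) -> AnnotationIndex:
    """Load a GENCODE-style GFF3/GTF into an :class:`AnnotationIndex`.

    Recognized feature types: gene, exon, CDS, UTR variants, and a small set
    of non-coding exonic types; children are attached to genes by Parent
    (GFF3) / gene_id (GTF) attributes.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[Gene] = []
    for gf in db.features_of_type("gene"):
        exons, cds, utrs, other = [], [], [], []
        for child in db.children(gf.id):
            span = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(span)
            elif child.featuretype == "CDS":
                cds.append(span)
            elif child.featuretype in _UTR_TYPES:
                utrs.append(span)
            elif child.featuretype in _OTHER_EXONIC_TYPES:
                other.append(span)
        biotype = (gf.attributes.get("gene_type") or gf.attributes.get("biotype") or ["protein_coding"])[0]
        genes.append(
            Gene(
                gene_id=gf.id,
                chromosome=gf.seqid,
                start=gf.start - 1,
                end=gf.end,
                strand=gf.strand if gf.strand in "+-" else "+",
                exons=tuple(exons),
                cds=tuple(cds),
                utrs=tuple(utrs),
                other_features=tuple(other),
                biotype=biotype,
            )
        )
    return AnnotationIndex(genes, promoter_length=promoter_length)
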