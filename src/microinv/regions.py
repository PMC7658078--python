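"""MI regions (MIRs) and genomic-context classification.

An MIR is the united region of overlapping MIs across individuals, with the
constraint that the MIR is at most ``tolerance`` (default 4) base pairs
longer than any one of its member MIs.  Every MI belongs to exactly one MIR;
an "MIR hit" is the number of MI alleles the MIR contains.

Context classification assigns each MIR exactly one region class with the
precedence CDS > UTR > other_exonic > intronic > intergenic_promoter >
intergenic, where candidate promoters are the 2000 bp strand-aware upstream
flank of a gene body and apply only to MIRs outside every gene body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .detect import MICall
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

#: Default slack of the MIR length constraint, in bp.
MIR_TOLERANCE = 4

REGION_CLASSES = (
    "CDS",
    "UTR",
    "other_exonic",
    "intronic",
    "intergenic_promoter",
    "intergenic",
)

#: Default candidate-promoter extent upstream of the gene body, in bp.
PROMOTER_LENGTH = 2000


@dataclass(frozen=True)
class MIR:
    """A micro-inversion region: the union of its member MI calls."""

    interval: GenomicInterval
    members: tuple[MICall, ...]

    @property
    def hits(self) -> int:
        """Number of MI alleles included within this MIR."""
        return len(self.members)

    @property
    def mir_id(self) -> str:
        return f"{self.interval.chromosome}:{self.interval.start}-{self.interval.end}"


def merge_mis_to_mirs(calls: Sequence[MICall], tolerance: int = MIR_TOLERANCE) -> list[MIR]:
    """Merge MI calls into MIRs, greedy left-to-right.

    Calls are processed sorted by (chromosome, start, end, individual).  A
    call joins the open MIR iff it overlaps the MIR's current union by at
    least 1 bp and the new union is at most ``tolerance`` bp longer than the
    shortest member (including the candidate); otherwise it starts a new MIR.
    Every call ends up in exactly one MIR.  Input must already be
    deduplicated per (individual, interval).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    ordered = sorted(calls, key=lambda c: (c.interval, c.individual))
    seen: set[tuple[str, GenomicInterval]] = set()
    for c in ordered:
        key = (c.individual, c.interval)
        if key in seen:
            raise ValueError(
                f"duplicate call for individual {c.individual} at {c.interval.to_1based()}; "
                "deduplicate per (individual, interval) first"
            )
        seen.add(key)

    mirs: list[MIR] = []
    members: list[MICall] = []
    union: GenomicInterval | None = None
    min_len = 0

    def close() -> None:
        nonlocal members, union
        if members:
            mirs.append(MIR(interval=union, members=tuple(members)))
        members, union = [], None

    for c in ordered:
        iv = c.interval
        if union is not None and union.overlaps(iv):
            new_union = union.union(iv)
            new_min = min(min_len, iv.length)
            if new_union.length <= new_min + tolerance:
                union = new_union
                min_len = new_min
                members.append(c)
                continue
        close()
        union, min_len, members = iv, iv.length, [c]
    close()
    return mirs


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    utrs: tuple[tuple[int, int], ...] = ()
    other_features: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for s, e in self.exons + self.cds + self.utrs + self.other_features:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: feature [{s},{e}) outside gene body")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gene body minus the exon union."""
        spans = sorted(self.exons)
        out = []
        cursor = self.start
        for s, e in spans:
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.end:
            out.append((cursor, self.end))
        return tuple(out)

    def promoter(self, length: int = PROMOTER_LENGTH) -> tuple[int, int]:
        """Strand-aware candidate promoter flank; never overlaps the gene body."""
        if self.strand == "+":
            return (max(0, self.start - length), self.start)
        return (self.end, self.end + length)


class AnnotationIndex:
    """Interval index over genes, exons, CDS, UTRs, promoters for fast overlap.

    Feature spans are validated to lie within their gene; promoters are
    derived, strand-aware, and by construction never overlap their own gene
    body (they may overlap a neighbouring gene).
    """

    def __init__(self, genes: Sequence[Gene], promoter_length: int = PROMOTER_LENGTH):
        self.genes = tuple(genes)
        self.promoter_length = promoter_length
        self._trees: dict[str, dict[str, IntervalTree]] = {}

        def _add(kind: str, chrom: str, s: int, e: int) -> None:
            if e <= s:
                return
            self._trees.setdefault(chrom, {}).setdefault(kind, IntervalTree()).addi(s, e)

        for g in self.genes:
            _add("gene", g.chromosome, g.start, g.end)
            for s, e in g.cds:
                _add("cds", g.chromosome, s, e)
            for s, e in g.utrs:
                _add("utr", g.chromosome, s, e)
            for s, e in g.exons + g.other_features:
                _add("exon", g.chromosome, s, e)
            ps, pe = g.promoter(promoter_length)
            _add("promoter", g.chromosome, ps, pe)

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(self._trees)

    def _overlaps(self, kind: str, iv: GenomicInterval) -> bool:
        trees = self._trees.get(iv.chromosome)
        if not trees or kind not in trees:
            return False
        return bool(trees[kind].overlap(iv.start, iv.end))

    def classify(self, iv: GenomicInterval) -> str:
        """Region class for an interval under the fixed precedence."""
        if iv.chromosome not in self._trees:
            logger.warning(
                "interval %s on a chromosome absent from the annotation; classified intergenic",
                iv.to_1based(),
            )
            return "intergenic"
        if self._overlaps("gene", iv):
            if self._overlaps("cds", iv):
                return "CDS"
            if self._overlaps("utr", iv):
                return "UTR"
            if self._overlaps("exon", iv):
                return "other_exonic"
            return "intronic"
        if self._overlaps("promoter", iv):
            return "intergenic_promoter"
        return "intergenic"


def classify_mir(mir: MIR, ann: AnnotationIndex) -> str:
    """Exactly one region class per MIR (precedence CDS > UTR > other_exonic >
    intronic > intergenic_promoter > intergenic)."""
    return ann.classify(mir.interval)


def _pct(part: int, whole: int, digits: int = 1) -> float | None:
    """Percentage rounded to ``digits`` decimals; None when the base is empty."""
    if whole == 0:
        return None
    return round(100.0 * part / whole, digits)


def context_summary_from_counts(class_counts: Mapping[str, int]) -> dict:
    """Hierarchical counts and percentages from per-class MIR counts.

    Percentages follow the reporting structure: genic/intergenic of the
    total; intronic vs exonic within genic; CDS/UTR/other within exonic;
    candidate promoter within intergenic.  Rounded to one decimal.
    """
    counts = {k: int(class_counts.get(k, 0)) for k in REGION_CLASSES}
    exonic = counts["CDS"] + counts["UTR"] + counts["other_exonic"]
    genic = exonic + counts["intronic"]
    intergenic = counts["intergenic_promoter"] + counts["intergenic"]
    total = genic + intergenic
    return {
        "class_counts": counts,
        "total": total,
        "genic": genic,
        "genic_pct": _pct(genic, total),
        "intergenic": intergenic,
        "intergenic_pct": _pct(intergenic, total),
        "intronic": counts["intronic"],
        "intronic_of_genic_pct": _pct(counts["intronic"], genic),
        "exonic": exonic,
        "exonic_of_genic_pct": _pct(exonic, genic),
        "cds_of_exonic_pct": _pct(counts["CDS"], exonic),
        "utr_of_exonic_pct": _pct(counts["UTR"], exonic),
        "other_of_exonic_pct": _pct(counts["other_exonic"], exonic),
        "promoter_of_intergenic_pct": _pct(counts["intergenic_promoter"], intergenic),
    }


def annotate_all(mirs: Sequence[MIR], ann: AnnotationIndex) -> dict:
    """Classify every MIR and summarize class counts with percentages."""
    counts = {k: 0 for k in REGION_CLASSES}
    for m in mirs:
        counts[classify_mir(m, ann)] += 1
    return context_summary_from_counts(counts)
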