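"""Synthetic data with planted micro-inversions.

Generates every input the pipeline needs at desk scale: a random reference
genome, a GENCODE-style gene annotation, population allele structure
(ancestral alleles segregating in all populations, derived alleles confined
to a designated clade), haploid presence/absence genotypes, and ~100 bp
reads in which each carried inverted allele appears as a reverse-complement
segment with exact anchoring flanks.

The generator guarantees that planted alleles are recoverable: inverted
segments are never palindromic, alleles on one chromosome are separated by
at least one read length (so each read carries at most one inversion), and
each allele's read layout is validated to admit a unique inversion
decomposition (the locus is resampled otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .detect import detect_inversion_in_read
from .intervals import GenomicInterval
from .regions import Gene, AnnotationIndex, PROMOTER_LENGTH

#: Planted allele length bounds (the MI definition).
ALLELE_MIN_LEN = 10
ALLELE_MAX_LEN = 99

_BASES = np.array(list("ACGT"))


class ReferenceGenome:
    """Chromosome name -> uppercase A/C/G/T sequence; every chromosome >= 200 bp."""

    def __init__(self, sequences: Mapping[str, str]):
        seqs = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            if len(seq) < 200:
                raise ValueError(f"chromosome {chrom}: length {len(seq)} < 200")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {chrom}: non-ACGT symbols present")
            seqs[chrom] = seq
        self.sequences: dict[str, str] = seqs

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


def generate_reference(
    n_chromosomes: int,
    lengths: int | Sequence[int],
    seed: int,
    max_homopolymer: int = 8,
) -> ReferenceGenome:
    """Random reference genome, deterministic for a given seed.

    Homopolymer runs longer than ``max_homopolymer`` are broken up to limit
    inversion boundary ambiguity.
    """
    if isinstance(lengths, int):
        lengths = [lengths] * n_chromosomes
    if len(lengths) != n_chromosomes:
        raise ValueError("one length per chromosome required")
    rng = np.random.default_rng(seed)
    sequences = {}
    for i, n in enumerate(lengths, start=1):
        chrom = f"chr{i}"
        if n <= 0:
            raise ValueError(f"chromosome {chrom}: non-positive length {n}")
        codes = rng.integers(0, 4, size=n)
        while True:
            bad = _homopolymer_positions(codes, max_homopolymer)
            if bad.size == 0:
                break
            codes[bad] = (codes[bad] + rng.integers(1, 4, size=bad.size)) % 4
        sequences[chrom] = "".join(_BASES[codes])
    return ReferenceGenome(sequences)


def _homopolymer_positions(codes: np.ndarray, cap: int) -> np.ndarray:
    """Positions that extend a homopolymer run beyond ``cap`` bases."""
    if codes.size <= cap:
        return np.array([], dtype=int)
    same = np.concatenate(([0], (codes[1:] == codes[:-1]).astype(int)))
    run = np.empty_like(same)
    run[0] = 1
    for i in range(1, same.size):  # short loop at desk-scale genome sizes
        run[i] = run[i - 1] + 1 if same[i] else 1
    return np.flatnonzero(run > cap)


def generate_annotation(
    ref: ReferenceGenome,
    n_genes: int,
    seed: int,
    promoter_length: int = PROMOTER_LENGTH,
    noncoding_fraction: float = 0.2,
) -> AnnotationIndex:
    """GENCODE-style synthetic annotation: multi-exon genes with CDS and UTRs.

    Each gene gets >= 2 exons (hence >= 1 intron), one CDS span inside an
    exon with UTR spans flanking it, mixed strands; a ``noncoding_fraction``
    of genes carry exons but no CDS/UTR (their exons drive the other_exonic
    class).  Genes are placed left to right with enough upstream spacing for
    candidate promoters.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(ref.sequences)
    min_gene, max_gene = 500, 1600
    genes: list[Gene] = []
    per_chrom = _spread(n_genes, [ref.lengths[c] for c in chroms])
    for chrom, want in zip(chroms, per_chrom):
        clen = ref.lengths[chrom]
        cursor = int(rng.integers(promoter_length, promoter_length + 200)) if clen > promoter_length + max_gene else 50
        placed = 0
        while placed < want:
            glen = int(rng.integers(min_gene, max_gene + 1))
            if cursor + glen > clen:
                break
            g0, g1 = cursor, cursor + glen
            e1 = int(rng.integers(120, max(121, glen // 3)))
            e2 = int(rng.integers(120, max(121, glen // 3)))
            exon1 = (g0, g0 + e1)
            exon2 = (g1 - e2, g1)
            strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() >= noncoding_fraction
            gid = f"gene{len(genes) + 1:04d}"
            if coding:
                c0 = g0 + int(rng.integers(20, e1 - 40))
                c1 = c0 + int(rng.integers(10, g0 + e1 - c0 - 9))
                genes.append(
                    Gene(
                        gene_id=gid,
                        chromosome=chrom,
                        start=g0,
                        end=g1,
                        strand=strand,
                        exons=(exon1, exon2),
                        cds=((c0, c1),),
                        utrs=((g0, c0), (c1, g0 + e1), exon2),
                        biotype="protein_coding",
                    )
                )
            else:
                genes.append(
                    Gene(
                        gene_id=gid,
                        chromosome=chrom,
                        start=g0,
                        end=g1,
                        strand=strand,
                        exons=(exon1, exon2),
                        biotype="miRNA",
                    )
                )
            placed += 1
            cursor = g1 + promoter_length + int(rng.integers(200, 1000))
        if placed < want:
            raise ValueError(
                f"chromosome {chrom} too short to place {want} genes (placed {placed})"
            )
    return AnnotationIndex(genes, promoter_length=promoter_length)


def _spread(total: int, weights: Sequence[int]) -> list[int]:
    w = np.asarray(weights, dtype=float)
    raw = np.floor(total * w / w.sum()).astype(int)
    for i in np.argsort(-(total * w / w.sum() - raw)):
        if raw.sum() >= total:
            break
        raw[i] += 1
    return raw.tolist()


# ---------------------------------------------------------------------------
# Population allele structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    super_population: str
    n_individuals: int


@dataclass(frozen=True)
class FrequencyModel:
    """How inverted-allele frequencies are assigned across populations.

    Ancestral alleles (a fraction ``ancestral_fraction`` of planted alleles)
    receive one frequency drawn from ``ancestral_freq_range`` that applies to
    every population; derived alleles receive a frequency drawn from
    ``derived_freq_range`` in the populations of one designated
    super-population clade (chosen per allele, or fixed via
    ``derived_superpopulation``) and zero elsewhere.  The default derived
    range keeps the between-clade frequency divergence at >= 0.3.
    """

    ancestral_fraction: float = 0.3
    ancestral_freq_range: tuple[float, float] = (0.05, 0.5)
    derived_freq_range: tuple[float, float] = (0.3, 0.6)
    derived_superpopulation: str | None = None


@dataclass(frozen=True)
class PlantedAllele:
    allele_id: str
    interval: GenomicInterval
    allele_class: str  # "ancestral" | "derived"

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    ``frequencies[allele_id][population]`` is the inverted-allele frequency;
    ``genotypes`` maps each individual to the (haploid presence/absence) set
    of planted alleles it carries; ``population_map`` maps individual ->
    (population, super-population).
    """

    alleles: list[PlantedAllele]
    frequencies: dict[str, dict[str, float]]
    genotypes: dict[str, frozenset[str]]
    population_map: dict[str, tuple[str, str]]

    def allele_by_id(self, allele_id: str) -> PlantedAllele:
        return next(a for a in self.alleles if a.allele_id == allele_id)


def plant_population_alleles(
    ref: ReferenceGenome,
    populations: Sequence[PopulationSpec],
    n_alleles: int,
    frequency_model: FrequencyModel | Mapping[str, float] | None = None,
    seed: int = 0,
    read_length: int = 100,
) -> SimTruth:
    """Plant inverted alleles and draw per-individual genotypes.

    Allele intervals (10-99 bp) are placed non-overlapping, at least one
    ``read_length`` apart on the same chromosome, non-palindromic, and
    validated to be uniquely recoverable from their emitted read (ambiguous
    loci are resampled).  Genotypes are independent Bernoulli draws per
    individual per allele at the population's frequency.

    ``frequency_model`` may be a :class:`FrequencyModel` (random clade-
    structured frequencies) or an explicit ``{population: frequency}``
    mapping applied to every allele.
    """
    if not populations:
        raise ValueError("at least one population required")
    rng = np.random.default_rng(seed)
    pop_names = [p.name for p in populations]
    superpops = sorted({p.super_population for p in populations})
    explicit = isinstance(frequency_model, Mapping)
    if frequency_model is None:
        frequency_model = FrequencyModel()
    if explicit:
        for p in pop_names:
            if not (0.0 <= frequency_model[p] <= 1.0):
                raise ValueError(f"frequency for {p} outside [0, 1]")

    intervals = _place_alleles(ref, n_alleles, read_length, rng)

    alleles: list[PlantedAllele] = []
    frequencies: dict[str, dict[str, float]] = {}
    for i, iv in enumerate(intervals, start=1):
        aid = f"MI{i:04d}"
        if explicit:
            freqs = {p: float(frequency_model[p]) for p in pop_names}
            klass = "ancestral" if all(v > 0 for v in freqs.values()) else "derived"
        else:
            fm: FrequencyModel = frequency_model
            if rng.random() < fm.ancestral_fraction:
                klass = "ancestral"
                f = float(rng.uniform(*fm.ancestral_freq_range))
                freqs = {p: f for p in pop_names}
            else:
                klass = "derived"
                clade = fm.derived_superpopulation or superpops[int(rng.integers(len(superpops)))]
                f = float(rng.uniform(*fm.derived_freq_range))
                freqs = {
                    p.name: (f if p.super_population == clade else 0.0) for p in populations
                }
        alleles.append(PlantedAllele(allele_id=aid, interval=iv, allele_class=klass))
        frequencies[aid] = freqs

    genotypes: dict[str, frozenset[str]] = {}
    population_map: dict[str, tuple[str, str]] = {}
    for spec in populations:
        for j in range(spec.n_individuals):
            ind = f"{spec.name}{j:04d}"
            population_map[ind] = (spec.name, spec.super_population)
            draws = rng.random(len(alleles))
            carried = frozenset(
                a.allele_id
                for a, u in zip(alleles, draws)
                if u < frequencies[a.allele_id][spec.name]
            )
            genotypes[ind] = carried
    return SimTruth(
        alleles=alleles,
        frequencies=frequencies,
        genotypes=genotypes,
        population_map=population_map,
    )


def _allele_read_window(iv: GenomicInterval, read_length: int) -> tuple[int, int]:
    """Deterministic centered read window [a, b) around a planted allele."""
    flank = read_length - iv.length
    left = flank // 2
    a = iv.start - left
    return a, a + read_length


def _place_alleles(
    ref: ReferenceGenome, n_alleles: int, read_length: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    chroms = sorted(ref.sequences)
    weights = np.array([ref.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[GenomicInterval] = []
    attempts = 0
    max_attempts = 200 * n_alleles + 1000
    # read emission needs > 10 bp of exact flank on each side of the allele
    max_len = min(ALLELE_MAX_LEN, read_length - 21)
    if max_len < ALLELE_MIN_LEN:
        raise ValueError(f"read_length {read_length} leaves no room for a 10 bp allele")
    while len(out) < n_alleles:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_alleles} alleles with >= {read_length} bp separation: "
                "requested alleles exceed placeable capacity"
            )
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        clen = ref.lengths[chrom]
        alen = int(rng.integers(ALLELE_MIN_LEN, max_len + 1))
        lo, hi = read_length, clen - read_length - alen
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        iv = GenomicInterval(chrom, start, start + alen)
        if any(
            not (iv.end + read_length <= s or e + read_length <= iv.start)
            for s, e in placed[chrom]
        ):
            continue
        seg = ref.fetch(chrom, iv.start, iv.end)
        if reverse_complement(seg) == seg:
            continue  # palindromic: undetectable in principle
        a, b = _allele_read_window(iv, read_length)
        read = (
            ref.fetch(chrom, a, iv.start)
            + reverse_complement(seg)
            + ref.fetch(chrom, iv.end, b)
        )
        hit = detect_inversion_in_read(read, ref, [GenomicInterval(chrom, a, b)])
        if hit is None or hit.inversion != iv:
            continue  # ambiguous decomposition: resample the locus
        placed[chrom].append((iv.start, iv.end))
        out.append(iv)
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimRead:
    """One simulated read; ``allele_id`` is None for background reads."""

    name: str
    sequence: str
    individual: str
    allele_id: str | None = None


def emit_reads(
    ref: ReferenceGenome,
    truth: SimTruth,
    read_length: int = 100,
    seed: int = 0,
    n_background: int = 50,
) -> list[SimRead]:
    """Emit reads for every individual in the truth set.

    For each carried allele one read is emitted whose middle segment is the
    reverse complement of the reference segment at the allele's interval,
    with exact reference flanks; ``n_background`` exact reference substrings
    are emitted per individual as background.  Read names are
    ``individual:allele|bg:serial`` so detection can attribute calls.
    """
    max_alen = max((a.length for a in truth.alleles), default=0)
    if read_length <= max_alen + 20:
        offender = max(truth.alleles, key=lambda a: a.length)
        raise ValueError(
            f"read_length {read_length} too small for allele {offender.allele_id} "
            f"(length {offender.length}): need > length + 20 for 10 bp flanks"
        )
    rng = np.random.default_rng(seed)
    chroms = sorted(ref.sequences)
    weights = np.array([ref.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    by_id = {a.allele_id: a for a in truth.alleles}
    reads: list[SimRead] = []
    for ind in sorted(truth.genotypes):
        serial = 0
        for aid in sorted(truth.genotypes[ind]):
            allele = by_id[aid]
            iv = allele.interval
            a, b = _allele_read_window(iv, read_length)
            seq = (
                ref.fetch(iv.chromosome, a, iv.start)
                + reverse_complement(ref.fetch(iv.chromosome, iv.start, iv.end))
                + ref.fetch(iv.chromosome, iv.end, b)
            )
            serial += 1
            reads.append(SimRead(f"{ind}:{aid}:{serial}", seq, ind, aid))
        for _ in range(n_background):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, ref.lengths[chrom] - read_length + 1))
            serial += 1
            reads.append(
                SimRead(
                    f"{ind}:bg:{serial}",
                    ref.fetch(chrom, start, start + read_length),
                    ind,
                    None,
                )
            )
    return reads
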