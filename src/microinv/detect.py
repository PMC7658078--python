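"""Micro-inversion (MI) detection.

A micro-inversion is a short chromosomal segment (here 10-99 bp) whose
sequence is replaced by its reverse complement relative to the reference.
Reads carrying an MI fail ordinary exact alignment, but decompose as

    read = ref[a, s) + revcomp(ref[s, e)) + ref[e, b)

with both anchoring flanks matching the reference.  This module provides

* :func:`detect_inversion_in_read` - find such a decomposition for one read
  within candidate reference windows (single-inversion model);
* :func:`scan_reads` - orchestrate detection over per-individual read
  collections, with k-mer-anchored candidate windows and per-individual
  deduplication (the same interval seen in several reads of one individual
  is one call with a support count);
* :func:`scan_pairwise_alignment` - scan gap-free pairwise genome alignment
  blocks for inverted segments (used for cross-species call sets, where
  inversions up to 125 bp are admitted);
* :func:`filter_mi` - apply the MI length definition (10-99 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")
_RC_TABLE = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]

#: MI length bounds from the working definition (< 100 bp, and segments
#: shorter than 10 bp are discarded as unreliable).
MIN_MI_LENGTH = 10
MAX_MI_LENGTH = 99


@dataclass(frozen=True)
class MICall:
    """One inverted allele observed in one individual.

    ``inverted_allele_sequence`` is the reverse complement of
    ``reference_allele_sequence``; palindromic segments (where the two would
    coincide) are never emitted because the inverted allele would be
    indistinguishable from the reference allele.
    """

    interval: GenomicInterval
    individual: str
    population: str
    reference_allele_sequence: str
    inverted_allele_sequence: str
    support: int = 1

    def __post_init__(self) -> None:
        ref = self.reference_allele_sequence.upper()
        inv = self.inverted_allele_sequence.upper()
        if len(ref) != self.interval.length:
            raise ValueError("reference allele sequence length != interval length")
        if inv != reverse_complement(ref):
            raise ValueError("inverted allele is not the reverse complement of the reference allele")
        if inv == ref:
            raise ValueError("palindromic inverted allele is indistinguishable from the reference")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class MIDetectionResult:
    """A single-inversion decomposition of a read against the reference."""

    inversion: GenomicInterval
    read_window: GenomicInterval
    flank_mismatches: int = 0

    def __post_init__(self) -> None:
        if not (
            self.read_window.chromosome == self.inversion.chromosome
            and self.read_window.start <= self.inversion.start
            and self.inversion.end <= self.read_window.end
        ):
            raise ValueError("inversion must lie within the read window")


def _validate_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not _DNA.issuperset(seq):
        bad = sorted(set(seq) - _DNA)
        raise ValueError(f"{what} contains non-ACGT symbols: {bad}")
    return seq


def detect_inversion_in_read(
    read: str,
    ref,
    candidate_windows: Sequence[GenomicInterval],
    *,
    min_len: int = MIN_MI_LENGTH,
    max_len: int = MAX_MI_LENGTH,
    min_flank: int = 10,
    max_flank_mismatches: int = 0,
) -> MIDetectionResult | None:
    """Detect a single inverted segment of ``min_len..max_len`` bp in a read.

    Searches every placement of the read inside each candidate window for a
    decomposition ``read = ref[a,s) + revcomp(ref[s,e)) + ref[e,b)`` with both
    flanks at least ``min_flank`` bp and at most ``max_flank_mismatches``
    flank mismatches (default 0, i.e. exact flanks).  Among valid
    decompositions the one with the smallest inversion start, then the
    shortest inverted segment, is returned (windows on different chromosomes
    are ordered by chromosome name).  Palindromic inverted segments are never
    reported.  Returns ``None`` when no decomposition exists.

    Parameters
    ----------
    read : str
        Read sequence (ACGT only).
    ref : ReferenceGenome or mapping of chromosome name -> sequence.
    candidate_windows : sequence of GenomicInterval
        Reference windows to search; each must be at least as long as the read.
    """
    read = _validate_dna(read, "read")
    if not candidate_windows:
        raise ValueError("candidate window list is empty")
    L = len(read)
    if L < 2 * min_flank + min_len:
        raise ValueError(
            f"read length {L} < {2 * min_flank + min_len}: too short for two "
            f"{min_flank} bp flanks plus a {min_len} bp inverted segment"
        )
    sequences = ref.sequences if hasattr(ref, "sequences") else ref

    best: tuple[str, int, int] | None = None  # (chrom, s, e-s)
    best_result: MIDetectionResult | None = None
    for win in candidate_windows:
        chrom_seq = sequences.get(win.chromosome)
        if chrom_seq is None:
            continue
        if win.length < L:
            continue
        for a in range(win.start, win.end - L + 1):
            res = _decompose_at(read, chrom_seq, a, min_len, max_len, min_flank, max_flank_mismatches)
            if res is None:
                continue
            s, e, mism = res
            key = (win.chromosome, s, e - s)
            if best is None or key < best:
                best = key
                best_result = MIDetectionResult(
                    inversion=GenomicInterval(win.chromosome, s, e),
                    read_window=GenomicInterval(win.chromosome, a, a + L),
                    flank_mismatches=mism,
                )
    return best_result


def _decompose_at(
    read: str,
    chrom_seq: str,
    a: int,
    min_len: int,
    max_len: int,
    min_flank: int,
    cap: int,
) -> tuple[int, int, int] | None:
    """Best (smallest s, then shortest) decomposition of ``read`` placed at ``a``.

    Returns (s, e, flank_mismatches) in chromosome coordinates, or None.
    """
    L = len(read)
    if a < 0 or a + L > len(chrom_seq):
        return None
    window = chrom_seq[a : a + L]
    if read == window:
        # Exact reference substring: any decomposition would require a
        # palindromic inverted segment, which is excluded.
        return None
    # revcomp(read[s:e]) == rc_read[L-e : L-s], so the inner loop needs no
    # per-candidate reverse complement.
    rc_read = _revcomp(read)
    if cap == 0:
        # Exact flanks: the inverted segment must cover the first and last
        # mismatch between read and reference window.
        lcp = _common_prefix(read, window)
        lcs = _common_suffix(read, window)
        s_lo, s_hi = min_flank, lcp
        for s_off in range(s_lo, s_hi + 1):
            e_lo = max(s_off + min_len, L - lcs)
            e_hi = min(s_off + max_len, L - min_flank)
            for e_off in range(e_lo, e_hi + 1):
                ref_seg = window[s_off:e_off]
                if ref_seg == rc_read[L - e_off : L - s_off] and ref_seg != read[s_off:e_off]:
                    return a + s_off, a + e_off, 0
        return None
    # Mismatch-tolerant flanks (cap > 0): full enumeration with counting.
    for s_off in range(min_flank, L - min_flank - min_len + 1):
        left_mm = sum(1 for x, y in zip(read[:s_off], window[:s_off]) if x != y)
        if left_mm > cap:
            continue
        e_hi = min(s_off + max_len, L - min_flank)
        for e_off in range(s_off + min_len, e_hi + 1):
            ref_seg = window[s_off:e_off]
            if ref_seg != rc_read[L - e_off : L - s_off] or ref_seg == read[s_off:e_off]:
                continue
            right_mm = sum(1 for x, y in zip(read[e_off:], window[e_off:]) if x != y)
            if left_mm + right_mm <= cap:
                return a + s_off, a + e_off, left_mm + right_mm
    return None


def _common_prefix(x: str, y: str) -> int:
    n = 0
    for cx, cy in zip(x, y):
        if cx != cy:
            break
        n += 1
    return n


def _common_suffix(x: str, y: str) -> int:
    n = 0
    for cx, cy in zip(reversed(x), reversed(y)):
        if cx != cy:
            break
        n += 1
    return n


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def candidate_windows_for_read(read: str, ref, k: int = 10) -> list[GenomicInterval]:
    """Mapper-style anchoring: windows where the read's first or last k-mer
    matches the reference exactly.

    For a prefix hit at p the window is ``[p, p+L)``; for a suffix hit at q it
    is ``[q+k-L, q+k)``, clipped to the chromosome.
    """
    L = len(read)
    sequences = ref.sequences if hasattr(ref, "sequences") else ref
    prefix, suffix = read[:k], read[-k:]
    wins: set[GenomicInterval] = set()
    for chrom, seq in sequences.items():
        n = len(seq)
        for p in _find_all(seq, prefix):
            a, b = p, min(p + L, n)
            if b - a >= L:
                wins.add(GenomicInterval(chrom, a, b))
        for q in _find_all(seq, suffix):
            a, b = max(q + k - L, 0), q + k
            if b - a >= L:
                wins.add(GenomicInterval(chrom, a, b))
    return sorted(wins)


class _KmerIndex:
    """Exact k-mer -> (chromosome, position) index over a reference.

    Built once per scan so per-read anchoring is a dict lookup instead of a
    substring search over every chromosome.
    """

    def __init__(self, sequences: Mapping[str, str], k: int):
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in sequences.items():
            for p in range(len(seq) - k + 1):
                index.setdefault(seq[p : p + k], []).append((chrom, p))
        self._index = index

    def windows_for_read(self, read: str, lengths: Mapping[str, int]) -> list[GenomicInterval]:
        L = len(read)
        k = self.k
        wins: set[GenomicInterval] = set()
        for chrom, p in self._index.get(read[:k], ()):
            if p + L <= lengths[chrom]:
                wins.add(GenomicInterval(chrom, p, p + L))
        for chrom, q in self._index.get(read[-k:], ()):
            if q + k - L >= 0:
                wins.add(GenomicInterval(chrom, q + k - L, q + k))
        return sorted(wins)


def _individual_of_read_name(name: str) -> str:
    return name.split(":", 1)[0]


def _population_of(population_map: Mapping, individual: str) -> str:
    entry = population_map[individual]
    if isinstance(entry, str):
        return entry
    return entry[0]


def scan_reads(
    reads,
    ref,
    population_map: Mapping,
    *,
    min_len: int = MIN_MI_LENGTH,
    max_len: int = MAX_MI_LENGTH,
    min_flank: int = 10,
    k: int = 10,
    max_flank_mismatches: int = 0,
) -> list[MICall]:
    """Detect MIs across read collections and deduplicate per individual.

    ``reads`` is an iterable of ``(name, sequence)`` pairs or objects with
    ``name``/``sequence`` attributes; the individual identifier is the read
    name up to the first ``:``.  An interval detected in several reads of the
    same individual yields one :class:`MICall` with ``support`` equal to the
    number of supporting reads; the same interval in different individuals
    yields one call per individual.  Reads whose individual is missing from
    ``population_map`` are skipped with a logged warning.

    Returns calls sorted by (chromosome, start, end, individual).
    """
    sequences = ref.sequences if hasattr(ref, "sequences") else ref
    lengths = {c: len(s) for c, s in sequences.items()}
    kmer_index = _KmerIndex(sequences, k)
    support: dict[tuple[str, GenomicInterval], int] = {}
    skipped = 0
    for item in reads:
        if hasattr(item, "name"):
            name, seq = item.name, item.sequence
        else:
            name, seq = item
        individual = _individual_of_read_name(name)
        if individual not in population_map:
            logger.warning("read %s: unknown individual %r, skipped", name, individual)
            skipped += 1
            continue
        seq = seq.upper()
        windows = kmer_index.windows_for_read(seq, lengths)
        if not windows:
            continue
        hit = detect_inversion_in_read(
            seq,
            sequences,
            windows,
            min_len=min_len,
            max_len=max_len,
            min_flank=min_flank,
            max_flank_mismatches=max_flank_mismatches,
        )
        if hit is None:
            continue
        key = (individual, hit.inversion)
        support[key] = support.get(key, 0) + 1
    if skipped:
        logger.warning("scan_reads: %d reads skipped (unknown individuals)", skipped)

    calls = []
    for (individual, iv), n in support.items():
        ref_seq = sequences[iv.chromosome][iv.start : iv.end]
        calls.append(
            MICall(
                interval=iv,
                individual=individual,
                population=_population_of(population_map, individual),
                reference_allele_sequence=ref_seq,
                inverted_allele_sequence=reverse_complement(ref_seq),
                support=n,
            )
        )
    calls.sort(key=lambda c: (c.interval, c.individual))
    return calls


@dataclass(frozen=True)
class AlignmentBlock:
    """A gap-free pairwise alignment block in reference coordinates."""

    chromosome: str
    ref_start: int
    ref_seq: str
    query_seq: str

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.query_seq):
            raise ValueError(
                f"alignment block {self.chromosome}:{self.ref_start}: "
                "reference and query sequences differ in length"
            )


def scan_pairwise_alignment(
    blocks: Iterable[AlignmentBlock],
    species: str = "species",
    *,
    min_len: int = MIN_MI_LENGTH,
    max_len: int = 125,
    min_flank: int = 5,
) -> list[MICall]:
    """Scan pairwise alignment blocks for inverted segments.

    Reports maximal runs where the query equals the reverse complement of the
    reference segment, flanked on both sides by at least ``min_flank``
    exactly-matching bases, with run length within ``[min_len, max_len]``
    (default 10-125 bp, the range used for cross-species scans).  A maximal
    run longer than ``max_len`` yields no call.  Palindromic runs are
    excluded.  Calls are attributed to ``species`` as the individual, one call
    per distinct interval.
    """
    found: dict[GenomicInterval, str] = {}
    for block in blocks:
        if isinstance(block, (tuple, list)):
            block = AlignmentBlock(*block)
        rseq = _validate_dna(block.ref_seq, "reference sequence")
        qseq = _validate_dna(block.query_seq, "query sequence")
        for i, j in _maximal_revcomp_runs(rseq, qseq, max_probe=max_len + 25):
            if not (min_len <= j - i <= max_len):
                continue
            if i < min_flank or j + min_flank > len(rseq):
                continue
            if rseq[i - min_flank : i] != qseq[i - min_flank : i]:
                continue
            if rseq[j : j + min_flank] != qseq[j : j + min_flank]:
                continue
            seg = rseq[i:j]
            if qseq[i:j] == seg:  # palindromic
                continue
            iv = GenomicInterval(block.chromosome, block.ref_start + i, block.ref_start + j)
            found[iv] = seg
    calls = [
        MICall(
            interval=iv,
            individual=species,
            population=species,
            reference_allele_sequence=seg,
            inverted_allele_sequence=reverse_complement(seg),
            support=1,
        )
        for iv, seg in found.items()
    ]
    calls.sort(key=lambda c: c.interval)
    return calls


def _maximal_revcomp_runs(rseq: str, qseq: str, max_probe: int) -> list[tuple[int, int]]:
    """All maximal intervals [i, j) with qseq[i:j] == revcomp(rseq[i:j]).

    Candidates are enumerated around mismatch runs (an inverted, non-palindromic
    segment necessarily contains a mismatch); intervals longer than
    ``max_probe`` are not searched, so callers should pass a probe bound
    comfortably above their reporting cap to see over-long runs and reject
    them rather than report a sub-run.
    """
    n = len(rseq)
    mismatch = [i for i in range(n) if rseq[i] != qseq[i]]
    if not mismatch:
        return []
    # Maximal mismatch runs.
    runs = []
    start = prev = mismatch[0]
    for m in mismatch[1:]:
        if m == prev + 1:
            prev = m
        else:
            runs.append((start, prev + 1))
            start = prev = m
    runs.append((start, prev + 1))

    rc_r = _revcomp(rseq)  # revcomp(rseq[i:j]) == rc_r[n-j:n-i]
    valid: set[tuple[int, int]] = set()
    for p, q in runs:
        for i in range(max(0, q - max_probe), p + 1):
            j_hi = min(n, i + max_probe)
            for j in range(max(q, i + 1), j_hi + 1):
                # Quick endpoint checks before the full slice comparison.
                if qseq[i] != _COMPLEMENT[rseq[j - 1]]:
                    continue
                if qseq[j - 1] != _COMPLEMENT[rseq[i]]:
                    continue
                if qseq[i:j] == rc_r[n - j : n - i]:
                    valid.add((i, j))
    return [
        (i, j)
        for (i, j) in sorted(valid)
        if not any((x <= i and j <= y) and (x, y) != (i, j) for (x, y) in valid)
    ]


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def filter_mi(
    calls: Sequence[MICall],
    min_len: int = MIN_MI_LENGTH,
    max_len: int = MAX_MI_LENGTH,
) -> list[MICall]:
    """Keep calls whose length is within [min_len, max_len], preserving order."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [c for c in calls if min_len <= c.length <= max_len]
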