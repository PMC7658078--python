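"""Genomic interval primitives (0-based, half-open)."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome.

    Coordinates are stored 0-based half-open; :meth:`to_1based` renders the
    1-based inclusive style used in genome-browser reports
    (e.g. ``chr11: 126,146,988-126,147,016``).
    """

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chromosome != other.chromosome:
            raise ValueError("cannot union intervals on different chromosomes")
        return GenomicInterval(
            self.chromosome, min(self.start, other.start), max(self.end, other.end)
        )

    def to_1based(self) -> str:
        return f"{self.chromosome}:{self.start + 1:,}-{self.end:,}"
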