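"""Genomic interval primitives.

All coordinates throughout the package are 0-based, half-open ``[start, end)``
on a named chromosome, following the BED convention. Strand is ``"+"`` or
``"-"``. For a minus-strand feature the 5' end is the *end* boundary and the
3' end is the *start* boundary; helpers below encapsulate that arithmetic so
strand handling never leaks into calling code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    id : str, optional
        Free-form identifier (gene id, TU id, ...).
    """

    chrom: str
    start: int
    end: int
    strand: str
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.id or self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """5' boundary coordinate (start on +, end on -)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """3' boundary coordinate (end on +, start on -)."""
        return self.end if self.strand == "+" else self.start

    def with_id(self, new_id: str) -> "GenomicInterval":
        return replace(self, id=new_id)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )


def mirror_interval(iv: GenomicInterval, chrom_len: int) -> GenomicInterval:
    """Reflect an interval through the chromosome midpoint and flip strand.

    Maps ``[a, b)`` to ``[L-b, L-a)``; used by strand-symmetry tests.
    """
    return GenomicInterval(
        chrom=iv.chrom,
        start=chrom_len - iv.end,
        end=chrom_len - iv.start,
        strand="-" if iv.strand == "+" else "+",
        id=iv.id,
    )
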