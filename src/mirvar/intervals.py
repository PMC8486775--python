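"""Genomic intervals in the package-wide 1-based, fully-closed convention.

Every coordinate that crosses a module boundary is 1-based and inclusive on
both ends; conversion from half-open 0-based BED happens in
:mod:`mirvar.io_formats` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def norm_chrom(chrom: str) -> str:
    """Normalise a chromosome name by stripping an optional ``chr`` prefix.

    Annotation sources mix ``chr18`` with bare ``18``; comparisons are done
    on the stripped form, the original spelling is kept for output.
    """
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class GenomicInterval:
    """A closed interval ``[start, end]`` on one chromosome, optionally stranded.

    Parameters
    ----------
    chrom : str
        Chromosome name as spelled in the source file.
    start, end : int
        1-based inclusive bounds, ``1 <= start <= end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    _key: str = field(init=False, repr=False, compare=False, default="")

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")
        object.__setattr__(self, "_key", norm_chrom(self.chrom))

    @property
    def chrom_key(self) -> str:
        return self._key

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict overlap: the two closed intervals share at least one base."""
        return (
            self.chrom_key == other.chrom_key
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom_key == other.chrom_key
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Distance in bases between two intervals; 0 when they overlap.

        Adjacent intervals are 1 base apart, so a variant 50 bp away from a
        precursor falls exactly at the edge of a 50 bp flanking window.
        Returns ``None`` for intervals on different chromosomes.
        """
        if self.chrom_key != other.chrom_key:
            return None
        if self.overlaps(other):
            return 0
        if other.start > self.end:
            return other.start - self.end
        return self.start - other.end
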