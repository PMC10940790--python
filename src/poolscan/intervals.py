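"""Genomic intervals and coordinate conventions.

All coordinates in this package are 1-based and inclusive at both ends,
matching the notation used for herring divergence loci in the literature
(e.g. Chr15:6,750,000-7,000,000 is a 250-kbp locus).  Interval length is
defined as ``end - start`` in base pairs — the convention under which the
printed sizes of every reported locus come out exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

_UNIT_BP = {"bp": 1.0, "kbp": 1e3, "Mb": 1e6}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval [start, end] on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome label (e.g. ``"Chr8"``).
    start, end : int
        1-based positions, inclusive; ``end >= start`` is required.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"end < start for {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError("negative start position")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def length(self, unit: str = "bp") -> float:
        """Interval length, ``end - start``, scaled to *unit* (bp|kbp|Mb)."""
        try:
            scale = _UNIT_BP[unit]
        except KeyError:
            raise ValueError(f"unknown unit {unit!r}; expected bp, kbp or Mb")
        return self.length_bp / scale

    def contains(self, chrom: str, pos) -> bool:
        """Vectorised membership test for position(s) on a chromosome."""
        if chrom != self.chrom:
            return False
        return (self.start <= pos) & (pos <= self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_length(iv: GenomicInterval, unit: str = "bp") -> float:
    """Length of *iv* as ``end - start`` in the requested unit."""
    return iv.length(unit)


def format_length(iv: GenomicInterval, unit: str = "bp") -> str:
    """Length formatted the way locus sizes are printed (one decimal for
    kbp/Mb, integer bp)."""
    v = iv.length(unit)
    if unit == "bp":
        return f"{int(v)} bp"
    return f"{v:.1f} {unit}"
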