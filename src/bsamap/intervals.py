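"""Genomic interval arithmetic.

Coordinates are 1-based inclusive (VCF convention) everywhere inside the
package; BED export converts to 0-based half-open. Interval length is
defined as ``end - start`` — the convention under which the candidate
region 76,294..2,305,623 bp measures 2.23 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "intersect_regions",
    "write_bed",
    "read_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome segment, 1-based inclusive endpoints."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 0:
            raise ValueError("interval start must be non-negative")

    @property
    def length(self) -> int:
        """Span in bp as ``end - start``."""
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


def intersect_regions(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise intersections of two interval lists.

    Commutative; the result has at most ``min(len(a), len(b))`` intervals
    when each input is internally non-overlapping.
    """
    out = []
    for x in a:
        for y in b:
            hit = x.intersection(y)
            if hit is not None:
                out.append(hit)
    return sorted(set(out))


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    # 1-based inclusive -> 0-based half-open
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append(GenomicInterval(chrom, int(start) + 1, int(end)))
    return out
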