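"""Genomic interval algebra on 0-based half-open coordinates.

Everything positional in the package — capture regions, exons, promoters,
loop anchors, variant positions — is expressed as a :class:`GenomicInterval`.
BED files are read natively; GTF input is converted from 1-based inclusive
on read (and back on write) by :mod:`mencrna.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "CaptureUniverse",
    "merge_intervals",
    "intersect_intervals",
    "total_length",
    "coverage_within",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with optional strand.

    Parameters
    ----------
    chrom
        Chromosome / contig name.
    start
        0-based inclusive start, ``>= 0``.
    end
        0-based exclusive end, ``> start``.
    strand
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge to a disjoint, sorted list covering the same base-pair set.

    Abutting intervals (``end == start``) merge, consistent with half-open
    coordinates. Strand is dropped (output is unstranded).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-pair intersection of two interval sets (each merged first)."""
    am = merge_intervals(a)
    bm = merge_intervals(b)
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(am) and j < len(bm):
        x, y = am[i], bm[j]
        if x.chrom != y.chrom:
            if (x.chrom, x.start) < (y.chrom, y.start):
                i += 1
            else:
                j += 1
            continue
        lo = max(x.start, y.start)
        hi = min(x.end, y.end)
        if lo < hi:
            out.append(GenomicInterval(x.chrom, lo, hi))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by a set of intervals, after merging."""
    return sum(iv.length for iv in merge_intervals(intervals))


@dataclass
class CaptureUniverse:
    """The union of capture-array target regions.

    All enrichment statistics are conditioned on this universe: feature
    coverage is measured inside it and the circular-permutation null rotates
    annotations within each region independently.
    """

    regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = merge_intervals(self.regions)
        if not self.regions:
            raise ValueError("capture universe is empty")
        # per-chromosome sorted starts/ends for fast point lookup
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        by: dict[str, list[tuple[int, int, int]]] = {}
        for idx, iv in enumerate(self.regions):
            by.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        for chrom, triples in by.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            idxs = [t[2] for t in triples]
            self._by_chrom[chrom] = (starts, ends, idxs)

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.regions)

    def region_index_at(self, chrom: str, pos: int) -> int | None:
        """Index (into ``self.regions``) of the region containing a point."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, idxs = entry
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        if k >= 0 and pos < ends[k]:
            return idxs[k]
        return None

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.region_index_at(chrom, pos) is not None


def coverage_within(
    feature: Sequence[GenomicInterval], universe: CaptureUniverse
) -> tuple[int, float]:
    """bp and fraction of the capture universe covered by a feature set.

    Returns ``(bp, fraction)`` where ``bp`` is the length of the merged
    feature intersected with the universe and ``fraction = bp / total_bp``.
    """
    if universe.total_bp == 0:
        raise ValueError("capture universe has zero total length")
    bp = total_length(intersect_intervals(feature, universe.regions))
    return bp, bp / universe.total_bp
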