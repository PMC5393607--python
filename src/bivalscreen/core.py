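"""Genomic interval primitives.

All coordinates are 0-based, half-open (BED convention). Every higher-level
stage — promoter-window construction, read counting, TF-peak intersection —
reduces to the three operations here: window arithmetic, pairwise overlap,
and overlap counting against an indexed read set.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "PromoterWindow",
    "IntervalIndex",
    "make_promoter_window",
    "overlaps",
    "count_overlapping",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval must be non-empty: [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene reduced to its canonical TSS (5'-most start site on its strand)."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True, slots=True)
class PromoterWindow:
    """Symmetric +/-flank window around a gene's TSS (clipped at chromosome edges)."""

    gene_id: str
    interval: GenomicInterval
    flank: int = 5000

    def __post_init__(self) -> None:
        if self.interval.length > 2 * self.flank:
            raise ValueError("promoter window longer than 2*flank")


def make_promoter_window(
    gene: GeneRecord, flank: int = 5000, chrom_length: int | None = None
) -> PromoterWindow:
    """Build the +/-`flank` bp promoter window around a gene's TSS.

    The window is strand-symmetric: [tss - flank, tss + flank), clipped to
    [0, chrom_length) when the chromosome length is known. A TSS beyond the
    chromosome end is rejected.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    if chrom_length is not None and gene.tss >= chrom_length:
        raise ValueError(
            f"TSS {gene.tss} of {gene.gene_id} beyond chromosome end {chrom_length}"
        )
    start = max(0, gene.tss - flank)
    end = gene.tss + flank
    if chrom_length is not None:
        end = min(chrom_length, end)
    interval = GenomicInterval(gene.chrom, start, end)
    return PromoterWindow(gene_id=gene.gene_id, interval=interval, flank=flank)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class IntervalIndex:
    """Per-chromosome sorted index for counting interval overlaps.

    For a query window the overlap count is
    ``n_chrom - #(end <= window.start) - #(start >= window.end)``:
    the two excluded sets are disjoint for non-empty intervals, so two
    binary searches per query replace the naive scan.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        n = 0
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            n += 1
        self.n_total = n
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[chrom] = np.sort(arr[:, 0])
            self._ends[chrom] = np.sort(arr[:, 1])

    @classmethod
    def from_arrays(
        cls, chroms: Sequence[str] | np.ndarray, starts: np.ndarray, ends: np.ndarray
    ) -> "IntervalIndex":
        """Build directly from parallel chrom/start/end arrays (no objects)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        chroms = np.asarray(chroms)
        if not (starts.shape == ends.shape == chroms.shape):
            raise ValueError("chroms, starts and ends must have equal length")
        if np.any(starts < 0) or np.any(ends <= starts):
            raise ValueError("intervals must satisfy 0 <= start < end")
        index = cls.__new__(cls)
        index.n_total = int(starts.size)
        index._starts = {}
        index._ends = {}
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            index._starts[str(chrom)] = np.sort(starts[mask])
            index._ends[str(chrom)] = np.sort(ends[mask])
        return index

    def count(self, window: GenomicInterval) -> int:
        starts = self._starts.get(window.chrom)
        if starts is None:
            return 0
        ends = self._ends[window.chrom]
        n = starts.size
        left_out = int(np.searchsorted(ends, window.start, side="right"))
        right_out = n - int(np.searchsorted(starts, window.end, side="left"))
        return n - left_out - right_out


def count_overlapping(
    reads: Sequence[GenomicInterval] | IntervalIndex, window: GenomicInterval
) -> int:
    """Number of reads sharing >= 1 bp with `window`.

    Accepts either a plain collection (indexed on the fly) or a prebuilt
    :class:`IntervalIndex` for repeated queries. Equals the naive scan.
    """
    index = reads if isinstance(reads, IntervalIndex) else IntervalIndex(reads)
    return index.count(window)
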