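"""Genomic-interval data model and the overlap query engine.

All coordinates are 0-based half-open (BED convention). Two intervals on the
same chromosome overlap when they share at least ``min_bp`` base pairs; with
the default ``min_bp=1`` this is the "at least 1 bp" rule used for every
peak/anchor/window intersection in the package. Adjacent half-open intervals
([0,10) vs [10,20)) do not overlap.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import ValidationError

DEFAULT_MIN_BP = 1


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome universe with lengths in bp."""

    chrom_lengths: dict[str, int]

    def __post_init__(self):
        if len(self.chrom_lengths) == 0:
            raise ValidationError("genome has no chromosomes")
        for name, length in self.chrom_lengths.items():
            if length < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = DEFAULT_MIN_BP) -> bool:
    """True iff a and b share >= min_bp base pairs on the same chromosome."""
    if min_bp < 1:
        raise ValidationError(f"min_bp must be >= 1, got {min_bp}")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


@dataclass(frozen=True)
class Peak:
    """A called binding region, optionally with score and narrowPeak summit."""

    interval: GenomicInterval
    name: str
    score: Optional[float] = None
    summit_offset: Optional[int] = None

    def __post_init__(self):
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.width
        ):
            raise ValidationError(
                f"peak {self.name!r}: summit offset {self.summit_offset} outside "
                f"[0, {self.interval.width})"
            )

    @property
    def representative_point(self) -> int:
        """Summit position when known, else the floored midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


class _IntervalIndex:
    """Per-chromosome sorted-start index with prefix-max ends.

    Query cost is O(log n + k') where k' is the number of candidates scanned;
    the prefix-max array lets the backward scan stop as soon as no earlier
    interval can still reach the query.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], np.ndarray, np.ndarray, list[int]]] = {}
        buckets: dict[str, list[tuple[int, int, int]]] = {}
        for idx, iv in enumerate(intervals):
            buckets.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        for chrom, rows in buckets.items():
            rows.sort()
            starts = [r[0] for r in rows]
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            idxs = [r[2] for r in rows]
            self._by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends), idxs)

    def query(self, iv: GenomicInterval, min_bp: int = DEFAULT_MIN_BP) -> list[int]:
        """Original indices of stored intervals overlapping iv by >= min_bp."""
        if min_bp < 1:
            raise ValidationError(f"min_bp must be >= 1, got {min_bp}")
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return []
        starts, ends, prefix_max_end, idxs = entry
        # candidates must start early enough to leave min_bp of shared ground
        hi = bisect.bisect_right(starts, iv.end - min_bp)
        hits = []
        for i in range(hi - 1, -1, -1):
            if prefix_max_end[i] - iv.start < min_bp:
                break
            if min(ends[i], iv.end) - max(starts[i], iv.start) >= min_bp:
                hits.append(idxs[i])
        hits.reverse()
        return hits


@dataclass
class PeakSet:
    """All peaks for one factor in one condition; sorted on construction."""

    factor: str
    condition: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValidationError(f"duplicate peak name {dup!r} in set {self.factor}")
        self._index: Optional[_IntervalIndex] = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def query(self, iv: GenomicInterval, min_bp: int = DEFAULT_MIN_BP) -> list[Peak]:
        """Peaks overlapping iv by >= min_bp, in genomic order."""
        if self._index is None:
            self._index = _IntervalIndex(self.intervals())
        return [self.peaks[i] for i in self._index.query(iv, min_bp)]


def overlap_query(
    query: GenomicInterval,
    subject: "PeakSet | Sequence[GenomicInterval]",
    min_bp: int = DEFAULT_MIN_BP,
) -> list:
    """All subject members overlapping the query, in genomic order.

    Accepts a PeakSet (returns Peaks) or a plain interval sequence (returns
    GenomicIntervals).
    """
    if isinstance(subject, PeakSet):
        return subject.query(query, min_bp)
    index = _IntervalIndex(list(subject))
    return [subject[i] for i in index.query(query, min_bp)]


@dataclass(frozen=True)
class Anchor:
    """One end of a chromatin loop."""

    interval: GenomicInterval
    side: int

    def __post_init__(self):
        if self.side not in (1, 2):
            raise ValidationError(f"anchor side must be 1 or 2, got {self.side}")


@dataclass(frozen=True)
class Loop:
    """A paired-anchor chromatin interaction, canonicalized on construction.

    Canonical order: (chrom, start, end) of anchor1 <= that of anchor2
    lexicographically; sides are renumbered accordingly, so canonicalization
    is idempotent and insensitive to the input anchor order.
    """

    anchor1: Anchor
    anchor2: Anchor
    loop_id: str
    score: Optional[float] = None

    def __post_init__(self):
        a, b = self.anchor1.interval, self.anchor2.interval
        if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
            object.__setattr__(self, "anchor1", Anchor(b, side=1))
            object.__setattr__(self, "anchor2", Anchor(a, side=2))
        else:
            object.__setattr__(self, "anchor1", Anchor(a, side=1))
            object.__setattr__(self, "anchor2", Anchor(b, side=2))

    @property
    def is_intrachromosomal(self) -> bool:
        return self.anchor1.interval.chrom == self.anchor2.interval.chrom

    @property
    def span(self) -> Optional[int]:
        """Midpoint-to-midpoint distance in bp; None across chromosomes."""
        if not self.is_intrachromosomal:
            return None
        return abs(self.anchor2.interval.midpoint - self.anchor1.interval.midpoint)


@dataclass
class LoopSet:
    """All loops called in one condition."""

    condition: str
    loops: list[Loop] = field(default_factory=list)

    def __post_init__(self):
        ids = [lp.loop_id for lp in self.loops]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate loop_id {dup!r} in LoopSet {self.condition!r}")

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self) -> Iterator[Loop]:
        return iter(self.loops)

    @property
    def n_interchromosomal(self) -> int:
        return sum(1 for lp in self.loops if not lp.is_intrachromosomal)


@dataclass(frozen=True)
class TSSRecord:
    """One gene's transcription start site (0-based) with strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative TSS {self.tss}")


@dataclass
class TSSTable:
    """Gene/TSS universe; gene ids unique."""

    records: list[TSSRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate gene_id {dup!r} in TSS table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TSSRecord]:
        return iter(self.records)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def subset(self, gene_ids: Iterable[str]) -> "TSSTable":
        wanted = set(gene_ids)
        return TSSTable([r for r in self.records if r.gene_id in wanted])

    def validate_against(self, genome: Genome) -> None:
        for r in self.records:
            if r.chrom not in genome:
                raise ValidationError(f"gene {r.gene_id!r}: unknown chromosome {r.chrom!r}")
            if r.tss >= genome.length_of(r.chrom):
                raise ValidationError(
                    f"gene {r.gene_id!r}: TSS {r.tss} beyond end of {r.chrom}"
                )
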