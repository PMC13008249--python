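"""Co-occupancy of two factors' peak sets and hormone-dependent binding dynamics.

Two peak sets A and B are compared by building the bipartite overlap graph
(edges between A and B peaks sharing >= min_bp) and taking its connected
components. Each component is a "shared site": a merged genomic region bound
by both factors. Reporting one shared-site count as a fraction of each set's
total matches the Venn-style semantics of factor co-occupancy figures; the
per-set counts of overlapping peaks are carried alongside because chains of
overlaps can make them differ from the cluster count.

The same machinery, relabeled, classifies treated-vs-untreated peak dynamics
into lost / conserved / gained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import ValidationError
from .intervals import (
    DEFAULT_MIN_BP,
    GenomicInterval,
    Peak,
    PeakSet,
    TSSTable,
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), unlike banker's round()."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SharedCluster:
    """One connected component of the A/B overlap graph, merged to its union."""

    interval: GenomicInterval
    a_peaks: tuple[Peak, ...]
    b_peaks: tuple[Peak, ...]


@dataclass
class OverlapPartition:
    """Partition of two peak sets into exclusive peaks and shared clusters."""

    a_only: PeakSet
    b_only: PeakSet
    shared_clusters: list[SharedCluster]
    n_a_total: int
    n_b_total: int

    @property
    def n_shared(self) -> int:
        return len(self.shared_clusters)

    @property
    def n_a_in_clusters(self) -> int:
        return sum(len(c.a_peaks) for c in self.shared_clusters)

    @property
    def n_b_in_clusters(self) -> int:
        return sum(len(c.b_peaks) for c in self.shared_clusters)

    @property
    def frac_of_a(self):
        """100 * n_shared / n_a_total; None when A is empty."""
        if self.n_a_total == 0:
            return None
        return 100.0 * self.n_shared / self.n_a_total

    @property
    def frac_of_b(self):
        if self.n_b_total == 0:
            return None
        return 100.0 * self.n_shared / self.n_b_total


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def partition_peaksets(a: PeakSet, b: PeakSet, min_bp: int = DEFAULT_MIN_BP) -> OverlapPartition:
    """Partition peak sets A and B into exclusive peaks and shared clusters."""
    if len(a) == 0 or len(b) == 0:
        warnings.warn(
            "partition_peaksets: empty input set, no shared clusters possible", stacklevel=2
        )
    n_a, n_b = len(a), len(b)
    uf = _UnionFind(n_a + n_b)  # A peaks 0..n_a-1, B peaks n_a..n_a+n_b-1
    touched_a, touched_b = set(), set()
    # query returns Peak objects; map identity to index for O(1) lookup
    a_pos = {id(p): i for i, p in enumerate(a.peaks)}
    for j, pb in enumerate(b.peaks):
        for pa in a.query(pb.interval, min_bp):
            i = a_pos[id(pa)]
            uf.union(i, n_a + j)
            touched_a.add(i)
            touched_b.add(j)

    components: dict[int, tuple[list[Peak], list[Peak]]] = {}
    for i in touched_a:
        components.setdefault(uf.find(i), ([], []))[0].append(a.peaks[i])
    for j in touched_b:
        components.setdefault(uf.find(n_a + j), ([], []))[1].append(b.peaks[j])

    clusters = []
    for a_peaks, b_peaks in components.values():
        members = a_peaks + b_peaks
        chrom = members[0].interval.chrom
        merged = GenomicInterval(
            chrom,
            min(p.interval.start for p in members),
            max(p.interval.end for p in members),
        )
        clusters.append(SharedCluster(merged, tuple(a_peaks), tuple(b_peaks)))
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))

    a_only = PeakSet(a.factor, a.condition, [p for i, p in enumerate(a.peaks) if i not in touched_a])
    b_only = PeakSet(b.factor, b.condition, [p for j, p in enumerate(b.peaks) if j not in touched_b])
    return OverlapPartition(a_only, b_only, clusters, n_a, n_b)


def overlap_percentages(p: OverlapPartition) -> dict:
    """Report row with shared counts and percentages, half-up at 1 decimal."""
    return {
        "n_a_total": p.n_a_total,
        "n_b_total": p.n_b_total,
        "n_shared": p.n_shared,
        "n_a_in_clusters": p.n_a_in_clusters,
        "n_b_in_clusters": p.n_b_in_clusters,
        "frac_of_a": None if p.frac_of_a is None else round_half_up(p.frac_of_a, 1),
        "frac_of_b": None if p.frac_of_b is None else round_half_up(p.frac_of_b, 1),
    }


@dataclass
class DynamicsPartition:
    """Lost / conserved / gained classification of a condition pair."""

    lost: PeakSet
    conserved_clusters: list[SharedCluster]
    gained: PeakSet
    n_before_total: int
    n_after_total: int

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_conserved(self) -> int:
        return len(self.conserved_clusters)

    @property
    def n_gained(self) -> int:
        return len(self.gained)


def classify_dynamics(before: PeakSet, after: PeakSet, min_bp: int = DEFAULT_MIN_BP) -> DynamicsPartition:
    """Classify peaks of a treated/untreated pair into lost/conserved/gained.

    Identical to partition_peaksets with before as A and after as B: lost are
    before-only peaks, gained after-only, conserved the shared clusters.
    """
    part = partition_peaksets(before, after, min_bp)
    return DynamicsPartition(
        lost=part.a_only,
        conserved_clusters=part.shared_clusters,
        gained=part.b_only,
        n_before_total=part.n_a_total,
        n_after_total=part.n_b_total,
    )


def tss_proximity_fraction(
    peaks: PeakSet, tss: TSSTable, max_distance_bp: int = 1000
) -> float:
    """Percentage of peaks whose summit/midpoint lies within max_distance_bp
    of the nearest TSS (absolute distance, strand-agnostic)."""
    import bisect

    if max_distance_bp < 0:
        raise ValidationError(f"max_distance_bp must be >= 0, got {max_distance_bp}")
    if len(tss) == 0:
        raise ValidationError("tss_proximity_fraction: empty TSS table")
    if len(peaks) == 0:
        raise ValidationError("tss_proximity_fraction: empty peak set")

    by_chrom: dict[str, list[int]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append(rec.tss)
    for positions in by_chrom.values():
        positions.sort()

    n_close = 0
    for peak in peaks:
        positions = by_chrom.get(peak.interval.chrom)
        if not positions:
            continue
        point = peak.representative_point
        k = bisect.bisect_left(positions, point)
        best = min(
            abs(point - positions[i]) for i in (k - 1, k) if 0 <= i < len(positions)
        )
        if best <= max_distance_bp:
            n_close += 1
    return 100.0 * n_close / len(peaks)


def enrichment_ratio(numerator_fraction: float, baseline_fraction: float) -> float:
    """Fold enrichment of one proportion over a baseline proportion."""
    if baseline_fraction <= 0:
        raise ValidationError(
            f"enrichment_ratio: baseline fraction must be > 0, got {baseline_fraction}"
        )
    return numerator_fraction / baseline_fraction
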