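"""Linking chromatin loops to promoters and classifying anchor occupancy.

The workflow mirrors a pairtobed-style integration: promoter windows are
built around each TSS (default -5 kb/+1 kb, strand-aware), loops are retained
when at least one anchor overlaps a window, each anchor of a retained loop is
annotated for factor occupancy (GRHL2 peak, PR peak, TSS window, their
combinations, or Other), and retained loops are reduced to unordered
anchor-pair configurations to ask how distal elements connect to promoters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cooccupancy import _UnionFind, round_half_up
from .errors import ValidationError
from .intervals import (
    DEFAULT_MIN_BP,
    Anchor,
    Genome,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
    TSSTable,
    _IntervalIndex,
)

ANCHOR_CATEGORIES = (
    "GRHL2",
    "PR",
    "TSS",
    "GRHL2+PR",
    "GRHL2+TSS",
    "PR+TSS",
    "GRHL2+PR+TSS",
    "Other",
)
PAIR_LABELS = ("GRHL2", "PR", "GRHL2+PR", "Other")


@dataclass(frozen=True)
class TSSWindow:
    gene_id: str
    interval: GenomicInterval


class TSSWindows:
    """Indexed collection of promoter windows."""

    def __init__(self, windows: Sequence[TSSWindow]):
        self.windows = list(windows)
        self._index = _IntervalIndex([w.interval for w in self.windows])

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def query(self, iv: GenomicInterval, min_bp: int = DEFAULT_MIN_BP) -> list[TSSWindow]:
        return [self.windows[i] for i in self._index.query(iv, min_bp)]

    def gene_ids(self) -> list[str]:
        return [w.gene_id for w in self.windows]


def make_tss_windows(
    tss: TSSTable,
    upstream_bp: int = 5000,
    downstream_bp: int = 1000,
    genome: Optional[Genome] = None,
    strand_aware: bool = True,
) -> TSSWindows:
    """Build promoter windows around each TSS.

    A + strand gene at t gets [t - upstream, t + downstream); a - strand gene
    the mirror image. With strand_aware=False every gene is treated as +
    strand (for replicating tools that ignore strand). Windows are clipped to
    [0, chromosome length) when a genome is bound.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValidationError("window extents must be >= 0")
    if upstream_bp == 0 and downstream_bp == 0:
        raise ValidationError("window extents cannot both be 0")
    if genome is not None:
        tss.validate_against(genome)
    windows = []
    for rec in tss:
        if strand_aware and rec.strand == "-":
            start, end = rec.tss - downstream_bp, rec.tss + upstream_bp
        else:
            start, end = rec.tss - upstream_bp, rec.tss + downstream_bp
        start = max(0, start)
        if genome is not None:
            end = min(end, genome.length_of(rec.chrom))
        if end <= start:
            warnings.warn(
                f"make_tss_windows: window for {rec.gene_id!r} empty after clipping, skipped",
                stacklevel=2,
            )
            continue
        windows.append(TSSWindow(rec.gene_id, GenomicInterval(rec.chrom, start, end)))
    return TSSWindows(windows)


@dataclass(frozen=True)
class AnchorAnnotation:
    """Occupancy flags and category label for one loop anchor."""

    loop_id: str
    side: int
    has_grhl2: bool
    has_pr: bool
    has_tss: bool
    category: str
    overlapping_gene_ids: tuple[str, ...] = ()

    @property
    def pair_label(self) -> str:
        """Peak-only label used for anchor-pair configurations (TSS ignored)."""
        if self.has_grhl2 and self.has_pr:
            return "GRHL2+PR"
        if self.has_grhl2:
            return "GRHL2"
        if self.has_pr:
            return "PR"
        return "Other"


def _category(has_grhl2: bool, has_pr: bool, has_tss: bool) -> str:
    parts = [
        name for flag, name in ((has_grhl2, "GRHL2"), (has_pr, "PR"), (has_tss, "TSS")) if flag
    ]
    return "+".join(parts) if parts else "Other"


def classify_anchor(
    anchor: Anchor,
    grhl2: PeakSet,
    pr: PeakSet,
    windows: TSSWindows,
    min_bp: int = DEFAULT_MIN_BP,
    loop_id: str = "",
) -> AnchorAnnotation:
    """Annotate one anchor with GRHL2/PR/TSS occupancy flags and category."""
    has_grhl2 = bool(grhl2.query(anchor.interval, min_bp))
    has_pr = bool(pr.query(anchor.interval, min_bp))
    hit_windows = windows.query(anchor.interval, min_bp)
    genes = tuple(dict.fromkeys(w.gene_id for w in hit_windows))
    return AnchorAnnotation(
        loop_id=loop_id,
        side=anchor.side,
        has_grhl2=has_grhl2,
        has_pr=has_pr,
        has_tss=bool(hit_windows),
        category=_category(has_grhl2, has_pr, bool(hit_windows)),
        overlapping_gene_ids=genes,
    )


@dataclass
class LinkedLoopReport:
    """Loops retained for having an anchor in a promoter window, both
    directions of the gene <-> loop mapping, and (once annotated) per-anchor
    occupancy."""

    retained_loops: list[Loop]
    gene_to_loops: dict[str, list[str]]
    loop_to_genes: dict[str, list[str]]
    n_genes_in: int
    annotations: list[AnchorAnnotation] = field(default_factory=list)

    @property
    def n_genes_linked(self) -> int:
        return len(self.gene_to_loops)

    @property
    def n_loops_linked(self) -> int:
        return len(self.retained_loops)


def link_loops_to_tss(
    loops: LoopSet, windows: TSSWindows, min_bp: int = DEFAULT_MIN_BP
) -> LinkedLoopReport:
    """Retain loops with >= 1 anchor overlapping >= 1 promoter window."""
    if len(windows) == 0:
        raise ValidationError("link_loops_to_tss: no TSS windows")
    retained: list[Loop] = []
    gene_to_loops: dict[str, list[str]] = {}
    loop_to_genes: dict[str, list[str]] = {}
    for lp in loops:
        hits = windows.query(lp.anchor1.interval, min_bp) + windows.query(
            lp.anchor2.interval, min_bp
        )
        if not hits:
            continue
        retained.append(lp)
        genes = list(dict.fromkeys(w.gene_id for w in hits))
        loop_to_genes[lp.loop_id] = genes
        for g in genes:
            gene_to_loops.setdefault(g, []).append(lp.loop_id)
    n_genes_in = len(set(windows.gene_ids()))
    return LinkedLoopReport(retained, gene_to_loops, loop_to_genes, n_genes_in)


def annotate_anchors(
    report: LinkedLoopReport,
    grhl2: PeakSet,
    pr: PeakSet,
    windows: TSSWindows,
    min_bp: int = DEFAULT_MIN_BP,
) -> LinkedLoopReport:
    """Classify both anchors of every retained loop; fills report.annotations."""
    annotations = []
    for lp in report.retained_loops:
        for anchor in (lp.anchor1, lp.anchor2):
            annotations.append(
                classify_anchor(anchor, grhl2, pr, windows, min_bp, loop_id=lp.loop_id)
            )
    report.annotations = annotations
    return report


def anchor_category_table(report: LinkedLoopReport) -> dict:
    """Counts and whole-number percentages per category over all anchors
    (two per retained loop)."""
    if report.retained_loops and not report.annotations:
        raise ValidationError("anchor_category_table: run annotate_anchors first")
    counts = {cat: 0 for cat in ANCHOR_CATEGORIES}
    for ann in report.annotations:
        counts[ann.category] += 1
    total = len(report.annotations)
    percentages = {
        cat: (round_half_up(100.0 * n / total, 0) if total else 0.0)
        for cat, n in counts.items()
    }
    return {"n_anchors": total, "counts": counts, "percentages": percentages}


@dataclass(frozen=True)
class LoopConfiguration:
    """One unordered anchor-pair label combination with its frequency."""

    pair_label: tuple[str, str]
    count: int
    frequency: float


@dataclass
class PairConfigurationResult:
    configurations: list[LoopConfiguration]
    n_loops: int
    frac_cobound_anchor: float  # fraction of loops with >= 1 GRHL2+PR anchor
    require_pr_anchor: bool


def pair_configuration_table(
    report: LinkedLoopReport, require_pr_anchor: bool = True
) -> PairConfigurationResult:
    """Reduce each retained loop to the unordered pair of peak-based anchor
    labels; optionally keep only loops with a PR peak on >= 1 anchor.

    Also reports the fraction of kept loops with at least one co-bound
    (GRHL2+PR) anchor.
    """
    if report.retained_loops and not report.annotations:
        raise ValidationError("pair_configuration_table: run annotate_anchors first")
    by_loop: dict[str, list[AnchorAnnotation]] = {}
    for ann in report.annotations:
        by_loop.setdefault(ann.loop_id, []).append(ann)

    counts: dict[tuple[str, str], int] = {}
    n_kept = 0
    n_cobound = 0
    for lp in report.retained_loops:
        anns = by_loop[lp.loop_id]
        if require_pr_anchor and not any(a.has_pr for a in anns):
            continue
        n_kept += 1
        labels = tuple(sorted(a.pair_label for a in anns))
        counts[labels] = counts.get(labels, 0) + 1
        if any(a.pair_label == "GRHL2+PR" for a in anns):
            n_cobound += 1

    configurations = [
        LoopConfiguration(pair, n, n / n_kept if n_kept else 0.0)
        for pair, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    frac = n_cobound / n_kept if n_kept else 0.0
    return PairConfigurationResult(configurations, n_kept, frac, require_pr_anchor)


@dataclass
class LoopSetMatch:
    n_a_only: int
    n_b_only: int
    n_shared: int  # connected components linking >= 1 loop from each side
    a_only_ids: list[str]
    b_only_ids: list[str]


def match_loopsets(a: LoopSet, b: LoopSet, min_bp: int = DEFAULT_MIN_BP) -> LoopSetMatch:
    """Match two loop sets: loops are linked when both canonical anchor pairs
    overlap (anchor1 with anchor1 AND anchor2 with anchor2); shared counts
    are connected components of the bipartite linkage graph."""
    n_a, n_b = len(a), len(b)
    uf = _UnionFind(n_a + n_b)
    touched_a, touched_b = set(), set()
    b_index1 = _IntervalIndex([lp.anchor1.interval for lp in b.loops])
    for i, la in enumerate(a.loops):
        for j in b_index1.query(la.anchor1.interval, min_bp):
            lb = b.loops[j]
            iv_a2, iv_b2 = la.anchor2.interval, lb.anchor2.interval
            if (
                iv_a2.chrom == iv_b2.chrom
                and min(iv_a2.end, iv_b2.end) - max(iv_a2.start, iv_b2.start) >= min_bp
            ):
                uf.union(i, n_a + j)
                touched_a.add(i)
                touched_b.add(j)
    components = {uf.find(i) for i in touched_a} | {uf.find(n_a + j) for j in touched_b}
    a_only = [lp.loop_id for i, lp in enumerate(a.loops) if i not in touched_a]
    b_only = [lp.loop_id for j, lp in enumerate(b.loops) if j not in touched_b]
    return LoopSetMatch(len(a_only), len(b_only), len(components), a_only, b_only)


DEFAULT_SPAN_BINS_KB = (0, 20, 50, 100, 200, 500)


@dataclass
class SpanSummary:
    spans_bp: dict[str, int]  # loop_id -> span (intra-chromosomal only)
    histogram: dict[str, int]  # bin label (kb) -> count
    max_span_bp: int
    modal_bin: str
    n_degenerate: int
    n_interchromosomal_excluded: int


def span_summary(loops: LoopSet, bins_kb: Sequence[float] = DEFAULT_SPAN_BINS_KB) -> SpanSummary:
    """Midpoint-to-midpoint span of each intra-chromosomal loop plus a
    histogram over kb bins (last bin open-ended)."""
    if len(loops) == 0:
        raise ValidationError("span_summary: empty loop set")
    spans = {lp.loop_id: lp.span for lp in loops if lp.is_intrachromosomal}
    n_inter = len(loops) - len(spans)
    if not spans:
        raise ValidationError("span_summary: no intra-chromosomal loops")
    n_degenerate = sum(1 for s in spans.values() if s == 0)
    if n_degenerate:
        warnings.warn(
            f"span_summary: {n_degenerate} degenerate loop(s) with span 0", stacklevel=2
        )
    edges = [float(e) for e in bins_kb]
    if sorted(edges) != edges or len(edges) < 2:
        raise ValidationError("span_summary: bins_kb must be >= 2 increasing edges")
    values_kb = np.array(list(spans.values()), dtype=float) / 1000.0
    counts, _ = np.histogram(values_kb, bins=edges)
    labels = [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)]
    histogram = dict(zip(labels, counts.tolist()))
    overflow = int((values_kb >= edges[-1]).sum())
    histogram[f">{edges[-1]:g}"] = overflow
    modal_bin = max(histogram, key=histogram.get)
    return SpanSummary(
        spans_bp=spans,
        histogram=histogram,
        max_span_bp=max(spans.values()),
        modal_bin=modal_bin,
        n_degenerate=n_degenerate,
        n_interchromosomal_excluded=n_inter,
    )
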