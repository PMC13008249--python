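# Methods

This note documents the models and procedures chromalink implements, the
parameters that matter, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED convention); BEDPE anchors the
same. TSS tables carry a 1-based `tss` column on disk (the common form of
annotation exports) and are converted to 0-based on ingest; the writer
inverts the conversion so round-trips are exact. Chromosome names are taken
verbatim — no "chr" normalization — because silent renaming corrupts overlap
counts; `TSSTable.validate_against(genome)` provides a strict check against
a bound genome.

Two intervals overlap when they share at least `min_bp` base pairs
(default 1), the standard criterion for peak intersection. Half-open
adjacency ([0,10) vs [10,20)) is not an overlap. The overlap engine is a
per-chromosome sorted-start array with prefix-maximum ends: a query binary-
searches the last candidate start, then scans backwards, stopping as soon as
the running maximum end can no longer reach the query. Cost is
O(log n + k') per query; correctness is property-tested against an all-pairs
scan.

## Co-occupancy partitioning

Given peak sets A and B, edges connect every A-peak/B-peak pair overlapping
by ≥ min_bp; *shared sites* are the connected components of this bipartite
graph (union-find), merged to the union interval of their members. A single
component can contain several peaks from one set (chained overlaps), so the
component count is the one self-consistent "shared sites" number that can be
expressed as a fraction of both totals; per-set counts of overlapping peaks
are reported alongside (`n_a_in_clusters`, `n_b_in_clusters`). Percentages
are 100·n_shared/total, rounded half-up to one decimal. An empty set yields
a zero-shared partition with a warning, and an undefined percentage is
reported as null rather than 0.

Binding dynamics across a treatment is the same partition relabeled:
condition-1-only peaks are *lost*, shared components *conserved*,
condition-2-only peaks *gained*. This identity is asserted as a property
test rather than assumed.

TSS proximity reduces each peak to a representative point — the narrowPeak
summit when present, else the floored midpoint — and reports the percentage
of peaks whose point lies within `max_distance_bp` (default 1,000) of the
nearest TSS, strand-agnostic. This is a deliberate simplification of
full genomic annotation hierarchies (exon/intron/UTR categories are out of
scope); it reproduces only the promoter-distance fraction.

## Loop–promoter integration

Promoter windows default to −5,000/+1,000 bp around the TSS and are
strand-aware: a minus-strand gene's window is the mirror image, so
"upstream" always means upstream of transcription. A strand-ignorant mode
exists for replicating tools that ignore strand. Windows are clipped to
chromosome bounds when a genome is bound; a window that clips to zero width
is skipped with a warning.

A loop is linked when ≥ 1 of its two anchors overlaps ≥ 1 window; both
directions of the gene↔loop mapping are reported. Anchors of retained loops
get three boolean flags (GRHL2 peak, PR peak, TSS window, each by ≥ min_bp
overlap with any member) and the derived category label
(GRHL2 / PR / TSS / pairwise and triple combinations / Other, where Other
means all three flags false). Category percentages round half-up to whole
numbers, matching how such donut-chart summaries are usually printed.

Anchor-pair configurations ignore the TSS flag: each anchor reduces to
GRHL2, PR, GRHL2+PR or Other by its two peak flags, and each loop to the
unordered pair of those labels. With `require_pr_anchor` (default on) only
loops with a PR peak on ≥ 1 anchor are counted, and the fraction of kept
loops carrying ≥ 1 co-bound (GRHL2+PR) anchor is reported — the headline
statistic for "co-binding on at least one regulatory element".

Loop sets from two conditions are matched with the strictest reading of
"loops overlap": after canonical ordering (anchor1 ≤ anchor2 genomically),
loops are linked iff anchor1 overlaps anchor1 AND anchor2 overlaps anchor2;
shared counts are connected components of that linkage. Spans are
midpoint-to-midpoint distances (the measurement is not otherwise pinned
down; midpoints are insensitive to anchor-width asymmetries);
inter-chromosomal loops are retained on ingest but flagged and excluded
from span statistics, since their span is undefined.

## Gene selection and signature scoring

A gene is co-regulated when padj < α in all three contrasts; α defaults to
0.05 and is echoed in every report, since the threshold is an analysis
choice, not a property of the data. The knockdown-dependence criterion is
operationalized as significance in a supplied interaction/difference
contrast table — how that table was fitted (e.g. a DESeq2 interaction term)
is upstream of this package. Direction comes from the sign of log2FC in the
sustained (24 h) response, the contrast that defines the signature's sense;
this is configurable. Genes with log2FC exactly 0 are excluded with a
warning; genes absent from a table are treated as non-significant.

Scoring is the mean-z method: per-gene z across samples with sample sd
(ddof = 1); up-score = mean z over up-genes present, down-score likewise;
composite = up − down, with a side that has no usable genes contributing 0.
Zero-variance genes are excluded with a warning. The composite is
re-standardized across samples and median-split, ties assigned to "high"
(z ≥ median) for determinism. If the composite is identical across samples
the split is undefined; groups are left unassigned with a warning rather
than fabricated. Mean-z is a declared stand-in for dedicated signature-
scoring packages whose exact configuration is not pinned down here; because
per-gene z-standardization absorbs gene-wise affine transforms, scores are
invariant to per-gene scaling/shifting of the input matrix (property-
tested).

## Synthetic data

The generator states a world and the tests check the pipeline recovers it;
nothing is tuned to outcomes. Exactness comes from layout, not luck:

- **Territories.** Each chromosome (default 3 × 10 Mb) is divided into a
  gene territory (first half), a loop territory (first 60%) and a peak
  territory (top 35%). Background peak sets never collide with loop
  anchors because they cannot share coordinates.
- **Peak sets.** Each of `n_sites` (default 1,000) sites draws
  Bernoulli(p_shared) (default 0.3): a success places one peak per factor,
  overlapping by ≥ 1 bp; a failure places the two factors' peaks in
  separate slots. Slots are fixed-pitch (5 kb) and shuffled, so no
  unplanned overlap is possible and the recovered shared fraction is the
  Bernoulli draw exactly. Widths are log-normal with median 400 bp
  (clipped to [50, 2000] bp), a realistic TF-peak scale; none of these are
  claimed to be empirical distributions. Condition pairs reuse the same
  machinery with an exact planted conserved count.
- **Loops.** Spans are log-uniform on [20, 500] kb (echoing the observed
  "up to 500 kb, mostly 50–100 kb" scale), anchors 5 kb wide. Each loop
  draws an unordered pair of anchor labels from a configurable mixture and,
  with probability q_tss, centers anchor 1 on a distinct gene's TSS.
  Factor peaks dictated by the labels are planted inside the anchors;
  placement is bounded rejection sampling that keeps every anchor ≥ 1 kb
  clear of all promoter windows (unless attached) and all previously
  placed anchors, erroring with the loop index if unsatisfiable. The span
  is redrawn per placement attempt so feasibility does not skew the
  mixture or attachment draws. Consequences: attachment genes are unique
  per loop, and anchor flags/configurations re-derive exactly.
- **DE tables.** Planted genes draw padj strictly below α in all three
  contrasts with the planted sign at effect size 2; every other gene fails
  a uniformly drawn non-empty subset of contrasts by construction, so
  selection recovers the plant exactly at any seed.
- **Expression.** High-group samples get +effect on up-genes and −effect
  on down-genes over N(0,1) noise (default effect 2 sd, 40 samples, half
  per group); low-group samples are pure noise.

Streams: every generator derives its own `numpy` Generator from
`SeedSequence([master_seed, crc32(generator_name)])`, so outputs are
bit-reproducible per seed and adding a generator never perturbs existing
streams.

What a green test does establish: the interval algebra, graph partitioning,
linking, classification and scoring are exact on inputs whose truth is
known. What it does not: realism of genomic clustering (real peaks cluster
in accessible chromatin; slots are uniform), multi-gene loop hubs (planted
attachments are one gene per loop, though the analysis code handles
many-to-many), read-level noise, or annotation-version effects — so
agreement with published counts on real data is not implied beyond the
arithmetic identities tested.

## Numerical choices and degenerate inputs

- Half-up decimal rounding for reported percentages (1 decimal for set
  fractions, whole numbers for anchor categories).
- Union-find with path halving for components; deterministic ordering of
  all outputs (genomic sort for clusters, count-then-label for
  configuration tables).
- Parse errors name the file and 1-based line number; schema errors name
  the missing column or duplicated id; empty files return empty containers
  with a warning rather than erroring.
- Degenerate loops (identical anchors, span 0) are counted and flagged;
  min_bp < 1 is rejected.

## Known limitations

- Shared-site semantics (connected components) is one defensible reading of
  a Venn-style "overlapping sites" count; alternatives (A-side peaks,
  B-side peaks) are exposed as `n_a_in_clusters`/`n_b_in_clusters` but are
  not the headline number.
- TSS proximity is point-to-point and strand-agnostic; it is not a full
  genomic annotator.
- The package does not fit DE models, call peaks or loops, or perform
  survival analysis; upstream tables are inputs, downstream clinical
  modelling is out of scope.
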