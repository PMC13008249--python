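"""Seeded generators for every input the pipeline consumes, with planted
ground truth recorded so recovery tests can assert exact counts.

Layout guarantees, not probabilities, make the truth exact. Each chromosome
is split into disjoint territories: gene promoters live in the first half,
loop anchors (and the peaks planted inside them) in the first 60%, and
background peak-set slots in the top 35%. Within the peak territory every
peak (or overlapping peak pair) gets its own fixed-pitch slot, so nothing
overlaps anything it was not planted to overlap. Loop anchors are placed by
bounded rejection sampling against all promoter windows and all previously
placed anchors, so an anchor carries a TSS flag if and only if it was
attached, and carries exactly the factor peaks its drawn configuration
dictates.

Determinism: every generator derives its own numpy Generator from
(master seed, CRC32 of the generator's name), so adding a generator never
perturbs the streams of existing ones and repeated calls are bit-identical.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .intervals import (
    Anchor,
    Genome,
    GenomicInterval,
    Loop,
    LoopSet,
    Peak,
    PeakSet,
    TSSRecord,
    TSSTable,
)
from .loops import TSSWindows, make_tss_windows

# genome territories (fractions of each chromosome)
GENE_TERRITORY = (0.02, 0.50)
LOOP_TERRITORY = (0.02, 0.60)
PEAK_TERRITORY = (0.65, 1.00)

PEAK_SLOT_PITCH = 5_000  # one planted peak (pair) per slot
PEAK_MIN_WIDTH = 50
PEAK_MAX_WIDTH = 2_000
ANCHOR_GUARD = 1_000  # clearance kept around every placed anchor


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass
class GenomeSpec:
    n_chrom: int = 3
    chrom_length: int = 10_000_000


@dataclass
class GeneSpec:
    n_genes: int = 200
    min_spacing: int = 50_000


@dataclass
class PeakSpec:
    n_sites: int = 1_000  # per-factor peak count; a fraction p_shared co-occupied
    p_shared: float = 0.3
    median_width: float = 400.0
    width_log_sd: float = 0.5


@dataclass
class DynamicsSpec:
    n_before: int = 800
    n_after: int = 600
    p_conserved: float = 0.25
    n_conserved: Optional[int] = None  # overrides p_conserved when set


@dataclass
class LoopSpec:
    n_loops: int = 200
    min_span_kb: float = 20.0
    max_span_kb: float = 500.0
    anchor_width: int = 5_000
    q_tss: float = 0.5
    # mixture over unordered anchor-pair label combinations
    config_mixture: dict = field(
        default_factory=lambda: {
            ("GRHL2+PR", "PR"): 0.25,
            ("GRHL2+PR", "Other"): 0.15,
            ("GRHL2", "PR"): 0.20,
            ("PR", "PR"): 0.15,
            ("GRHL2", "Other"): 0.10,
            ("Other", "Other"): 0.15,
        }
    )


@dataclass
class DESpec:
    n_genes: int = 500
    n_planted: int = 40
    effect_size: float = 2.0
    alpha: float = 0.05
    p_up: float = 0.5


@dataclass
class ExpressionSpec:
    n_samples: int = 40
    effect_size: float = 2.0
    n_background_genes: int = 50


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)
    dynamics: DynamicsSpec = field(default_factory=DynamicsSpec)
    loops: LoopSpec = field(default_factory=LoopSpec)
    de: DESpec = field(default_factory=DESpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loops"]["config_mixture"] = {
            "|".join(k): v for k, v in self.loops.config_mixture.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build a config from a (possibly partial) nested mapping, e.g. a
        parsed YAML/JSON file; unknown keys raise, missing keys keep their
        defaults. Mixture keys may be given as "LABEL|LABEL" strings."""
        sections = {
            "genome": GenomeSpec,
            "genes": GeneSpec,
            "peaks": PeakSpec,
            "dynamics": DynamicsSpec,
            "loops": LoopSpec,
            "de": DESpec,
            "expression": ExpressionSpec,
        }
        kwargs: dict = {}
        for key, value in data.items():
            if key == "seed":
                kwargs["seed"] = int(value)
            elif key in sections:
                spec_cls = sections[key]
                known = spec_cls.__dataclass_fields__
                unknown = set(value) - set(known)
                if unknown:
                    raise ValidationError(
                        f"config section {key!r}: unknown option(s) {sorted(unknown)}"
                    )
                if key == "loops" and "config_mixture" in value:
                    value = dict(value)
                    value["config_mixture"] = {
                        tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                        for k, v in value["config_mixture"].items()
                    }
                kwargs[key] = spec_cls(**value)
            else:
                raise ValidationError(f"unknown config section {key!r}")
        return cls(**kwargs)


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML (or JSON, a YAML subset) file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping at top level")
    return SimulationConfig.from_dict(data)


@dataclass
class GroundTruth:
    """Planted facts, keyed so tests can re-derive them from the files."""

    shared_site_names: list[str] = field(default_factory=list)
    n_sites: int = 0
    dynamics_counts: dict = field(default_factory=dict)
    loop_configs: dict = field(default_factory=dict)  # loop_id -> sorted pair label
    loop_attached_gene: dict = field(default_factory=dict)  # loop_id -> gene_id or None
    coregulated: dict = field(default_factory=dict)  # gene_id -> "up"/"down"
    sample_groups: dict = field(default_factory=dict)  # sample_id -> "high"/"low"

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# genome + genes


def gen_genome_and_genes(cfg: SimulationConfig) -> tuple[Genome, TSSTable]:
    """Uniformly spaced TSSs (>= min_spacing apart) in the gene territory."""
    gspec, genes = cfg.genome, cfg.genes
    genome = Genome({f"chr{i + 1}": gspec.chrom_length for i in range(gspec.n_chrom)})
    rng = _rng(cfg.seed, "genome_and_genes")
    chroms = genome.chrom_names
    per_chrom = [genes.n_genes // len(chroms)] * len(chroms)
    for i in range(genes.n_genes % len(chroms)):
        per_chrom[i] += 1
    records = []
    gene_idx = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        lo = int(GENE_TERRITORY[0] * gspec.chrom_length)
        hi = int(GENE_TERRITORY[1] * gspec.chrom_length)
        slack = (hi - lo) - (k - 1) * genes.min_spacing
        if slack <= 0:
            raise ValidationError(
                f"gen_genome_and_genes: cannot fit {k} TSSs at spacing "
                f"{genes.min_spacing} on {chrom}"
            )
        offsets = np.sort(rng.integers(0, slack, size=k))
        for j, off in enumerate(offsets):
            records.append(
                TSSRecord(
                    gene_id=f"g{gene_idx:05d}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    tss=int(lo + off + j * genes.min_spacing),
                )
            )
            gene_idx += 1
    return genome, TSSTable(records)


# ---------------------------------------------------------------------------
# peak sets


class _SlotAllocator:
    """Fixed-pitch, non-overlapping slots in the peak territory, shuffled."""

    def __init__(self, genome: Genome, rng: np.random.Generator, pitch: int = PEAK_SLOT_PITCH):
        slots = []
        for chrom in genome.chrom_names:
            length = genome.length_of(chrom)
            lo = int(PEAK_TERRITORY[0] * length)
            hi = int(PEAK_TERRITORY[1] * length) - pitch
            slots.extend((chrom, s) for s in range(lo, hi, pitch))
        rng.shuffle(slots)
        self._slots = slots
        self._next = 0
        self.pitch = pitch

    def take(self) -> tuple[str, int]:
        if self._next >= len(self._slots):
            raise ValidationError(
                "synthetic genome too small: ran out of non-overlapping peak slots"
            )
        slot = self._slots[self._next]
        self._next += 1
        return slot


def _draw_width(rng: np.random.Generator, spec: PeakSpec) -> int:
    w = rng.lognormal(mean=math.log(spec.median_width), sigma=spec.width_log_sd)
    return int(np.clip(round(w), PEAK_MIN_WIDTH, PEAK_MAX_WIDTH))


def _planted_pair(
    rng: np.random.Generator, spec: PeakSpec, chrom: str, slot_start: int
) -> tuple[GenomicInterval, GenomicInterval]:
    """Two intervals overlapping by >= 1 bp, confined to one slot."""
    wa, wb = _draw_width(rng, spec), _draw_width(rng, spec)
    a_start = slot_start + 1000
    offset = int(rng.integers(0, wa))  # b starts inside a -> overlap >= 1
    return (
        GenomicInterval(chrom, a_start, a_start + wa),
        GenomicInterval(chrom, a_start + offset, a_start + offset + wb),
    )


def _solo_interval(
    rng: np.random.Generator, spec: PeakSpec, chrom: str, slot_start: int
) -> GenomicInterval:
    w = _draw_width(rng, spec)
    start = slot_start + 1000
    return GenomicInterval(chrom, start, start + w)


def gen_peaksets(
    cfg: SimulationConfig, genome: Genome, factor_a: str = "GRHL2", factor_b: str = "PR"
) -> tuple[PeakSet, PeakSet, GroundTruth]:
    """Two peak sets of n_sites peaks each; a planted Bernoulli(p_shared)
    fraction of sites carries one overlapping peak from each factor."""
    spec = cfg.peaks
    if not (0 <= spec.p_shared <= 1):
        raise ValidationError(f"p_shared must be in [0, 1], got {spec.p_shared}")
    rng = _rng(cfg.seed, "peaksets")
    slots = _SlotAllocator(genome, rng)
    a_peaks, b_peaks = [], []
    truth = GroundTruth(n_sites=spec.n_sites)
    for i in range(spec.n_sites):
        shared = rng.random() < spec.p_shared
        chrom, start = slots.take()
        if shared:
            iv_a, iv_b = _planted_pair(rng, spec, chrom, start)
            a_peaks.append(Peak(iv_a, name=f"{factor_a}_site{i}"))
            b_peaks.append(Peak(iv_b, name=f"{factor_b}_site{i}"))
            truth.shared_site_names.append(f"site{i}")
        else:
            a_peaks.append(Peak(_solo_interval(rng, spec, chrom, start), name=f"{factor_a}_site{i}"))
            chrom2, start2 = slots.take()
            b_peaks.append(
                Peak(_solo_interval(rng, spec, chrom2, start2), name=f"{factor_b}_site{i}")
            )
    return (
        PeakSet(factor_a, "simulated", a_peaks),
        PeakSet(factor_b, "simulated", b_peaks),
        truth,
    )


def gen_condition_pair(
    cfg: SimulationConfig, genome: Genome, factor: str = "GRHL2"
) -> tuple[PeakSet, PeakSet, GroundTruth]:
    """Before/after peak sets with an exactly planted conserved count."""
    spec = cfg.dynamics
    if spec.n_conserved is not None:
        n_cons = spec.n_conserved
    else:
        n_cons = int(round(spec.p_conserved * min(spec.n_before, spec.n_after)))
    if n_cons > min(spec.n_before, spec.n_after):
        raise ValidationError(
            f"n_conserved={n_cons} exceeds a condition's total "
            f"({spec.n_before}/{spec.n_after})"
        )
    rng = _rng(cfg.seed, "condition_pair")
    slots = _SlotAllocator(genome, rng)
    pspec = cfg.peaks
    before, after = [], []
    for i in range(n_cons):
        chrom, start = slots.take()
        iv_b, iv_a = _planted_pair(rng, pspec, chrom, start)
        before.append(Peak(iv_b, name=f"{factor}_cons{i}"))
        after.append(Peak(iv_a, name=f"{factor}_cons{i}"))
    for i in range(spec.n_before - n_cons):
        chrom, start = slots.take()
        before.append(Peak(_solo_interval(rng, pspec, chrom, start), name=f"{factor}_lost{i}"))
    for i in range(spec.n_after - n_cons):
        chrom, start = slots.take()
        after.append(Peak(_solo_interval(rng, pspec, chrom, start), name=f"{factor}_gain{i}"))
    truth = GroundTruth(
        dynamics_counts={
            "n_before": spec.n_before,
            "n_after": spec.n_after,
            "n_conserved": n_cons,
            "n_lost": spec.n_before - n_cons,
            "n_gained": spec.n_after - n_cons,
        }
    )
    return (
        PeakSet(factor, "untreated", before),
        PeakSet(factor, "treated", after),
        truth,
    )


# ---------------------------------------------------------------------------
# loops


class _UsedRegions:
    """Per-chromosome list of claimed intervals with a clearance guard."""

    def __init__(self, guard: int = ANCHOR_GUARD):
        self.guard = guard
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def clashes(self, iv: GenomicInterval) -> bool:
        for s, e in self._by_chrom.get(iv.chrom, ()):
            if min(e, iv.end) - max(s, iv.start) > -self.guard:
                return True
        return False

    def claim(self, iv: GenomicInterval) -> None:
        self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))


def _window_clash(windows: TSSWindows, iv: GenomicInterval, guard: int) -> bool:
    probe = GenomicInterval(iv.chrom, max(0, iv.start - guard), iv.end + guard)
    return bool(windows.query(probe))


def _plant_anchor_peaks(
    rng: np.random.Generator,
    label: str,
    anchor_iv: GenomicInterval,
    loop_id: str,
    side: int,
    grhl2_peaks: list[Peak],
    pr_peaks: list[Peak],
) -> None:
    """Place the factor peaks a label dictates strictly inside the anchor."""
    if label not in ("GRHL2", "PR", "GRHL2+PR"):
        return
    width = int(rng.integers(200, 600))
    center = anchor_iv.midpoint
    g_iv = GenomicInterval(anchor_iv.chrom, center - width // 2, center - width // 2 + width)
    if label in ("GRHL2", "GRHL2+PR"):
        grhl2_peaks.append(Peak(g_iv, name=f"GRHL2_{loop_id}_a{side}"))
    if label == "PR":
        pr_peaks.append(Peak(g_iv, name=f"PR_{loop_id}_a{side}"))
    elif label == "GRHL2+PR":
        off = int(rng.integers(0, width))  # overlaps the GRHL2 peak by >= 1 bp
        p_iv = GenomicInterval(anchor_iv.chrom, g_iv.start + off, g_iv.start + off + width)
        pr_peaks.append(Peak(p_iv, name=f"PR_{loop_id}_a{side}"))


def gen_loops(
    cfg: SimulationConfig,
    genome: Genome,
    tss: TSSTable,
    background_grhl2: Optional[PeakSet] = None,
    background_pr: Optional[PeakSet] = None,
    max_retries: int = 200,
) -> tuple[LoopSet, PeakSet, PeakSet, GroundTruth]:
    """Loops with planted anchor-pair configurations and TSS attachment.

    Anchor-local factor peaks are generated here (and merged with optional
    background sets, which live in a disjoint genome territory), so each
    anchor's occupancy flags are exact by construction. Pair labels come
    from {GRHL2, PR, GRHL2+PR, Other} ("Other": no factor peak planted);
    with probability q_tss anchor 1 is centered on a distinct randomly
    chosen gene's TSS.
    """
    spec = cfg.loops
    weights = np.array(list(spec.config_mixture.values()), dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError("loop config_mixture weights must sum to 1")
    pairs = list(spec.config_mixture.keys())
    rng = _rng(cfg.seed, "loops")
    windows = make_tss_windows(tss, genome=genome)
    used = _UsedRegions()
    genes = list(tss)
    available_gene_idx = list(range(len(genes)))
    aw = spec.anchor_width

    grhl2_peaks: list[Peak] = []
    pr_peaks: list[Peak] = []
    loops: list[Loop] = []
    truth = GroundTruth()

    def place_free_anchor(chrom_hint=None, near=None, span=None) -> Optional[GenomicInterval]:
        """One free-floating anchor: clear of every promoter window and every
        previously claimed region. With near/span set, place at +-span of it."""
        for _ in range(max_retries):
            if near is not None:
                direction = 1 if rng.random() < 0.5 else -1
                start = near.start + direction * span
                if start < 0 or start + aw > int(LOOP_TERRITORY[1] * genome.length_of(near.chrom)):
                    start = near.start - direction * span
                if start < 0 or start + aw > int(LOOP_TERRITORY[1] * genome.length_of(near.chrom)):
                    return None
                iv = GenomicInterval(near.chrom, start, start + aw)
            else:
                chrom = chrom_hint or genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
                lo = int(LOOP_TERRITORY[0] * genome.length_of(chrom))
                hi = int(LOOP_TERRITORY[1] * genome.length_of(chrom)) - aw
                iv = GenomicInterval(chrom, *(lambda s: (s, s + aw))(int(rng.integers(lo, hi))))
            if not _window_clash(windows, iv, used.guard) and not used.clashes(iv):
                return iv
            if near is not None:
                return None  # position is fully determined; no point retrying
        return None

    for i in range(spec.n_loops):
        loop_id = f"loop{i:04d}"
        pair = pairs[int(rng.choice(len(pairs), p=weights))]
        labels = list(pair)
        rng.shuffle(labels)
        attach = rng.random() < spec.q_tss

        iv1 = iv2 = None
        gene_id = None
        for _attempt in range(max_retries):
            # span redrawn per attempt: placement feasibility must not skew
            # the mixture or attachment draws above
            span = int(
                round(
                    10
                    ** rng.uniform(math.log10(spec.min_span_kb), math.log10(spec.max_span_kb))
                    * 1000
                )
            )
            if attach:
                if not available_gene_idx:
                    raise ValidationError(
                        f"gen_loops: loop {i}: no unclaimed gene left for TSS attachment"
                    )
                pick = int(rng.integers(0, len(available_gene_idx)))
                rec = genes[available_gene_idx[pick]]
                cand1 = GenomicInterval(rec.chrom, rec.tss - aw // 2, rec.tss - aw // 2 + aw)
                if used.clashes(cand1):
                    continue
                cand2 = place_free_anchor(near=cand1, span=span)
                if cand2 is None:
                    continue
                iv1, iv2, gene_id = cand1, cand2, rec.gene_id
                available_gene_idx.pop(pick)
                break
            else:
                cand1 = place_free_anchor()
                if cand1 is None:
                    continue
                cand2 = place_free_anchor(near=cand1, span=span)
                if cand2 is None:
                    continue
                iv1, iv2 = cand1, cand2
                break
        if iv1 is None or iv2 is None:
            raise ValidationError(f"gen_loops: unsatisfiable placement for loop index {i}")

        used.claim(iv1)
        used.claim(iv2)
        _plant_anchor_peaks(rng, labels[0], iv1, loop_id, 1, grhl2_peaks, pr_peaks)
        _plant_anchor_peaks(rng, labels[1], iv2, loop_id, 2, grhl2_peaks, pr_peaks)
        loops.append(Loop(Anchor(iv1, 1), Anchor(iv2, 2), loop_id=loop_id))
        truth.loop_configs[loop_id] = sorted(pair)
        truth.loop_attached_gene[loop_id] = gene_id

    if background_grhl2 is not None:
        grhl2_peaks.extend(background_grhl2.peaks)
    if background_pr is not None:
        pr_peaks.extend(background_pr.peaks)
    return (
        LoopSet("simulated", loops),
        PeakSet("GRHL2", "simulated", grhl2_peaks),
        PeakSet("PR", "simulated", pr_peaks),
        truth,
    )


# ---------------------------------------------------------------------------
# differential expression + expression matrix


def gen_de_tables(cfg: SimulationConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Three DE contrast tables with n_planted triple-significant genes.

    Planted genes draw padj strictly below alpha in every contrast; every
    other gene fails at least one contrast by construction (a uniformly
    drawn non-empty subset of contrasts gets padj >= alpha).
    """
    spec = cfg.de
    if spec.n_planted > spec.n_genes:
        raise ValidationError("n_planted cannot exceed n_genes")
    rng = _rng(cfg.seed, "de_tables")
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    planted = sorted(rng.choice(spec.n_genes, size=spec.n_planted, replace=False).tolist())
    planted_set = set(planted)
    directions = {}
    contrast_names = ("response_4h", "response_24h", "interaction")
    frames = {name: {"gene_id": [], "log2fc": [], "pvalue": [], "padj": []} for name in contrast_names}
    for gi, gene in enumerate(gene_ids):
        if gi in planted_set:
            sign = 1.0 if rng.random() < spec.p_up else -1.0
            directions[gene] = "up" if sign > 0 else "down"
            padjs = rng.uniform(1e-8, spec.alpha * 0.99, size=3)
            lfcs = sign * (spec.effect_size + np.abs(rng.normal(0, 1, size=3)))
        else:
            fail_mask = int(rng.integers(1, 8))  # non-empty subset of the 3 contrasts
            padjs, lfcs = [], []
            for k in range(3):
                if fail_mask >> k & 1:
                    padjs.append(rng.uniform(spec.alpha, 1.0))
                else:
                    padjs.append(rng.uniform(1e-8, spec.alpha * 0.99))
                lfcs.append(rng.normal(0, 1))
        for k, name in enumerate(contrast_names):
            frames[name]["gene_id"].append(gene)
            frames[name]["log2fc"].append(float(lfcs[k]))
            frames[name]["padj"].append(float(padjs[k]))
            frames[name]["pvalue"].append(float(padjs[k] * rng.uniform(0.1, 1.0)))
    tables = {}
    for name in contrast_names:
        df = pd.DataFrame(frames[name]).set_index("gene_id")
        df.attrs["contrast"] = name
        tables[name] = df
    truth = GroundTruth(coregulated=directions)
    return tables, truth


def gen_expression(
    cfg: SimulationConfig, up_genes: set[str], down_genes: set[str]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Genes x samples matrix with a planted high/low group structure.

    High-group samples get +effect on up genes and -effect on down genes
    over N(0,1) noise; low-group samples are pure noise.
    """
    spec = cfg.expression
    rng = _rng(cfg.seed, "expression")
    samples = [f"s{i:03d}" for i in range(spec.n_samples)]
    n_high = spec.n_samples // 2
    order = rng.permutation(spec.n_samples)
    groups = {samples[i]: ("high" if rank < n_high else "low") for rank, i in enumerate(order)}
    sig_genes = sorted(up_genes) + sorted(down_genes)
    bg_genes = [f"bg{i:04d}" for i in range(spec.n_background_genes)]
    all_genes = sig_genes + bg_genes
    data = rng.normal(0.0, 1.0, size=(len(all_genes), spec.n_samples))
    high_cols = np.array([groups[s] == "high" for s in samples])
    for r, g in enumerate(all_genes):
        if g in up_genes:
            data[r, high_cols] += spec.effect_size
        elif g in down_genes:
            data[r, high_cols] -= spec.effect_size
    expr = pd.DataFrame(data, index=pd.Index(all_genes, name="gene_id"), columns=samples)
    return expr, GroundTruth(sample_groups=groups)
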