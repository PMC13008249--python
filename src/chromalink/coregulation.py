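"""Selection of co-regulated genes across three DE contrasts and composite
signature scoring of expression matrices.

A gene counts as co-regulated by the two factors when its adjusted p-value is
below ``alpha`` in all three supplied contrasts: the acute hormone response
(4 h), the sustained response (24 h), and the knockdown-dependence contrast
(how the response changes when the pioneer factor is depleted). Direction
(up/down) is read from the sign of the log2 fold change in the sustained
response by default.

Scoring uses the mean-z method: expression is z-standardized per gene across
samples; a sample's up-score (down-score) is the mean z over the signature's
up (down) genes present in the matrix; the composite is up minus down, then
standardized across samples and median-split into high/low groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

DEFAULT_ALPHA = 0.05
CONTRASTS = ("response_4h", "response_24h", "interaction")


@dataclass
class CoregulatedGeneSet:
    """Genes significant in all three contrasts, with regulation direction."""

    genes: dict[str, str]  # gene_id -> "up" | "down"
    alpha: float
    direction_contrast: str = "response_24h"

    @property
    def n(self) -> int:
        return len(self.genes)

    def up_genes(self) -> set[str]:
        return {g for g, d in self.genes.items() if d == "up"}

    def down_genes(self) -> set[str]:
        return {g for g, d in self.genes.items() if d == "down"}


@dataclass
class Signature:
    """Up/down gene lists scored separately and combined."""

    up_genes: set[str]
    down_genes: set[str]

    def __post_init__(self):
        if self.up_genes & self.down_genes:
            raise ValidationError(
                f"signature genes in both directions: {sorted(self.up_genes & self.down_genes)[:5]}"
            )
        if not (self.up_genes or self.down_genes):
            raise ValidationError("signature is empty")


def _check_de_table(df: pd.DataFrame, label: str) -> None:
    for col in ("log2fc", "padj"):
        if col not in df.columns:
            raise SchemaError(f"DE table {label!r}: missing column {col!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"DE table {label!r}: duplicate gene {dup!r}")


def select_coregulated(
    de_4h: pd.DataFrame,
    de_24h: pd.DataFrame,
    de_interaction: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    direction_contrast: str = "response_24h",
) -> CoregulatedGeneSet:
    """Select genes with padj < alpha in all three contrasts.

    Tables are DataFrames indexed by gene_id with columns log2fc, pvalue,
    padj (see io.read_de_table). Genes absent from a table are treated as
    non-significant. Genes whose direction-contrast log2fc is exactly 0 are
    excluded with a warning.
    """
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    tables = {"response_4h": de_4h, "response_24h": de_24h, "interaction": de_interaction}
    if direction_contrast not in tables:
        raise ValidationError(
            f"direction_contrast must be one of {sorted(tables)}, got {direction_contrast!r}"
        )
    for label, df in tables.items():
        _check_de_table(df, label)

    selected = None
    for df in tables.values():
        sig = set(df.index[df["padj"].notna() & (df["padj"] < alpha)])
        selected = sig if selected is None else (selected & sig)

    dir_table = tables[direction_contrast]
    genes: dict[str, str] = {}
    n_zero = 0
    for g in sorted(selected):
        lfc = float(dir_table.loc[g, "log2fc"])
        if lfc > 0:
            genes[g] = "up"
        elif lfc < 0:
            genes[g] = "down"
        else:
            n_zero += 1
    if n_zero:
        warnings.warn(
            f"select_coregulated: excluded {n_zero} gene(s) with log2fc == 0 in "
            f"{direction_contrast}",
            stacklevel=2,
        )
    return CoregulatedGeneSet(genes=genes, alpha=alpha, direction_contrast=direction_contrast)


def build_signature(cgs: CoregulatedGeneSet) -> Signature:
    """Partition a co-regulated gene set into an up/down signature."""
    if cgs.n == 0:
        raise ValidationError("cannot build a signature from an empty gene set")
    up, down = cgs.up_genes(), cgs.down_genes()
    if not up or not down:
        warnings.warn(
            "build_signature: one direction is empty; composite reduces to a single side",
            stacklevel=2,
        )
    return Signature(up_genes=up, down_genes=down)


@dataclass
class SampleScore:
    sample_id: str
    up_score: float
    down_score: float
    composite: float
    z: float = float("nan")
    group: str = ""


def _zscore_rows(expr: pd.DataFrame, genes: set[str]) -> pd.DataFrame:
    """Per-gene z across samples (sample sd, ddof=1) for the genes present
    with positive variance; zero-variance genes dropped with a warning."""
    present = expr.loc[expr.index.intersection(sorted(genes))]
    if present.empty:
        return present
    sd = present.std(axis=1, ddof=1)
    flat = sd[(sd == 0) | sd.isna()].index
    if len(flat):
        warnings.warn(
            f"score_samples: excluded {len(flat)} zero-variance gene(s): "
            f"{', '.join(map(str, flat[:5]))}",
            stacklevel=3,
        )
        present = present.drop(index=flat)
        sd = sd.drop(index=flat)
    return present.sub(present.mean(axis=1), axis=0).div(sd, axis=0)


def score_samples(expr: pd.DataFrame, sig: Signature) -> list[SampleScore]:
    """Composite signature score per sample of a genes x samples matrix.

    composite = mean-z over up genes minus mean-z over down genes (a side
    with no usable genes contributes 0); the composite is then standardized
    across samples and median-split into high/low groups.
    """
    if expr.shape[1] < 2:
        raise ValidationError("score_samples: need at least 2 samples")
    z_up = _zscore_rows(expr, sig.up_genes)
    z_down = _zscore_rows(expr, sig.down_genes)
    if z_up.empty and z_down.empty:
        missing = sorted(sig.up_genes | sig.down_genes)
        raise ValidationError(
            "score_samples: no usable signature gene in the expression matrix; "
            f"missing/flat: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    samples = list(expr.columns)
    up = z_up.mean(axis=0) if not z_up.empty else pd.Series(0.0, index=samples)
    down = z_down.mean(axis=0) if not z_down.empty else pd.Series(0.0, index=samples)
    composite = up - down

    comp = composite.to_numpy(dtype=float)
    sd = comp.std(ddof=1)
    z = (comp - comp.mean()) / sd if sd > 0 else np.full_like(comp, np.nan)
    scores = [
        SampleScore(
            sample_id=str(s),
            up_score=float(up[s]),
            down_score=float(down[s]),
            composite=float(composite[s]),
            z=float(z[i]),
        )
        for i, s in enumerate(samples)
    ]
    try:
        return median_split(scores)
    except ValidationError:
        warnings.warn(
            "score_samples: composite identical across samples, high/low split undefined",
            stacklevel=2,
        )
        return scores


def median_split(scores: list[SampleScore]) -> list[SampleScore]:
    """Label samples high/low at the median of z (ties -> high)."""
    if len(scores) < 2:
        raise ValidationError("median_split: need at least 2 samples")
    z = np.array([s.z for s in scores], dtype=float)
    if np.isnan(z).any() or np.allclose(z, z[0]):
        raise ValidationError("median_split: all scores identical, split undefined")
    med = float(np.median(z))
    for s in scores:
        s.group = "high" if s.z >= med else "low"
    return scores


def scores_to_frame(scores: list[SampleScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "up_score": [s.up_score for s in scores],
            "down_score": [s.down_score for s in scores],
            "composite": [s.composite for s in scores],
            "z": [s.z for s in scores],
            "group": [s.group for s in scores],
        }
    )
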