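"""Readers and writers for BED/narrowPeak, BEDPE and the TSV tables.

BED-family parsing is line-based so that malformed input can be reported with
its 1-based line number, which downstream pipelines rely on when triaging bad
exports. TSV tables (TSS, differential expression, expression matrices) go
through pandas with explicit schema validation.

Coordinate conventions: BED/BEDPE files are 0-based half-open on disk and in
memory. The TSS table's ``tss`` column is 1-based on disk (as in most
annotation exports) and converted to 0-based on ingest; the writer inverts
the conversion, so round-trips are exact.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from .errors import ParseError, SchemaError
from .intervals import (
    Anchor,
    GenomicInterval,
    Loop,
    LoopSet,
    Peak,
    PeakSet,
    TSSRecord,
    TSSTable,
)

DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "padj")


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {token!r}") from None


def _parse_interval(chrom, start_tok, end_tok, path, lineno) -> GenomicInterval:
    start = _parse_int(start_tok, path, lineno, "start")
    end = _parse_int(end_tok, path, lineno, "end")
    if start < 0:
        raise ParseError(path, lineno, f"negative start {start}")
    if start >= end:
        raise ParseError(path, lineno, f"start {start} >= end {end}")
    return GenomicInterval(chrom, start, end)


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path, factor: str = "peaks", condition: str = "") -> PeakSet:
    """Read BED3/BED6 or ENCODE narrowPeak (10 columns) into a PeakSet.

    Missing name columns are auto-filled as ``<factor>_<index>``; a 10-column
    file is treated as narrowPeak and its summit offset (column 10, -1 for
    "no summit") is attached to each peak.
    """
    peaks = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >= 3 tab-separated columns, got {len(fields)}")
        interval = _parse_interval(fields[0], fields[1], fields[2], path, lineno)
        name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
        if name is None:
            name = f"{factor}_{len(peaks)}"
        score = None
        if len(fields) >= 5 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score: {fields[4]!r}") from None
        summit = None
        if len(fields) >= 10:  # narrowPeak
            summit_val = _parse_int(fields[9], path, lineno, "summit offset")
            if summit_val >= 0:
                if summit_val >= interval.width:
                    raise ParseError(
                        path, lineno, f"summit offset {summit_val} outside peak of width {interval.width}"
                    )
                summit = summit_val
        peaks.append(Peak(interval, name=name, score=score, summit_offset=summit))
    if not peaks:
        warnings.warn(f"{path}: empty BED file, returning empty PeakSet", stacklevel=2)
    return PeakSet(factor=factor, condition=condition, peaks=peaks)


def write_bed(peakset: PeakSet, path) -> None:
    """Write a PeakSet as BED6 (narrowPeak when any summit is recorded)."""
    narrow = any(p.summit_offset is not None for p in peakset)
    with open(path, "w") as fh:
        for p in peakset:
            iv = p.interval
            score = "0" if p.score is None else repr(p.score)
            if narrow:
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{score}\t.\t0\t-1\t-1\t{summit}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{score}\t.\n")


def read_bedpe(path, condition: str = "") -> LoopSet:
    """Read >= 6-column BEDPE into a canonicalized LoopSet.

    Loop ids come from column 7 when present, else are autogenerated.
    Inter-chromosomal rows are accepted and counted with a warning; they are
    excluded from span statistics downstream.
    """
    loops = []
    n_inter = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(path, lineno, f"expected >= 6 tab-separated columns, got {len(fields)}")
        iv1 = _parse_interval(fields[0], fields[1], fields[2], path, lineno)
        iv2 = _parse_interval(fields[3], fields[4], fields[5], path, lineno)
        loop_id = fields[6] if len(fields) >= 7 and fields[6] not in ("", ".") else f"loop_{len(loops)}"
        score = None
        if len(fields) >= 8 and fields[7] not in ("", "."):
            try:
                score = float(fields[7])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score: {fields[7]!r}") from None
        loop = Loop(Anchor(iv1, 1), Anchor(iv2, 2), loop_id=loop_id, score=score)
        if not loop.is_intrachromosomal:
            n_inter += 1
        loops.append(loop)
    if n_inter:
        warnings.warn(
            f"{path}: {n_inter} inter-chromosomal loop(s) retained but excluded from span statistics",
            stacklevel=2,
        )
    if not loops:
        warnings.warn(f"{path}: empty BEDPE file, returning empty LoopSet", stacklevel=2)
    return LoopSet(condition=condition, loops=loops)


def write_bedpe(loopset: LoopSet, path) -> None:
    with open(path, "w") as fh:
        for lp in loopset:
            a, b = lp.anchor1.interval, lp.anchor2.interval
            score = "." if lp.score is None else repr(lp.score)
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{lp.loop_id}\t{score}\n"
            )


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def read_tss_table(path) -> TSSTable:
    """Read a TSV of (gene_id, chrom, strand, tss); tss is 1-based on disk."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    _require_columns(df, ("gene_id", "chrom", "strand", "tss"), path)
    dups = df["gene_id"][df["gene_id"].duplicated()]
    if not dups.empty:
        raise SchemaError(f"{path}: duplicated gene_id {dups.iloc[0]!r}")
    records = [
        TSSRecord(gene_id=row.gene_id, chrom=row.chrom, strand=row.strand, tss=int(row.tss) - 1)
        for row in df.itertuples(index=False)
    ]
    return TSSTable(records)


def write_tss_table(tss: TSSTable, path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in tss],
            "chrom": [r.chrom for r in tss],
            "strand": [r.strand for r in tss],
            "tss": [r.tss + 1 for r in tss],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path, contrast: str = "") -> pd.DataFrame:
    """Read a differential-expression TSV (gene_id, log2fc/log2FC, pvalue, padj).

    Returns a DataFrame indexed by gene_id with attrs['contrast'] set.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df = df.rename(columns={"log2FC": "log2fc", "log2FoldChange": "log2fc"})
    _require_columns(df, DE_COLUMNS, path)
    dups = df["gene_id"][df["gene_id"].duplicated()]
    if not dups.empty:
        raise SchemaError(f"{path}: duplicated gene_id {dups.iloc[0]!r}")
    bad = df[(df["pvalue"] < 0) | (df["pvalue"] > 1)]
    if not bad.empty:
        raise SchemaError(f"{path}: pvalue outside [0, 1] for gene {bad['gene_id'].iloc[0]!r}")
    out = df.set_index("gene_id")[["log2fc", "pvalue", "padj"]]
    out.attrs["contrast"] = contrast
    return out


def write_de_table(df: pd.DataFrame, path) -> None:
    df.reset_index().rename(columns={"index": "gene_id"}).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expression matrix has no sample columns")
    dups = df["gene_id"][df["gene_id"].duplicated()]
    if not dups.empty:
        raise SchemaError(f"{path}: duplicated gene_id {dups.iloc[0]!r}")
    return df.set_index("gene_id")


def write_expression(df: pd.DataFrame, path) -> None:
    df.rename_axis("gene_id").to_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(report: dict, path) -> None:
    """Write a JSON report atomically (temp file + rename)."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tmp.replace(path)
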