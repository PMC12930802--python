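"""Readers and writers for every external format the pipeline touches.

All tabular dialects are header-bearing TSV read/written with pandas.
Coordinates in files are 0-based half-open (end - start equals the segment
length), matching how sizes are computed internally; read and write are
therefore exact inverses on canonical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome import (
    CatalogRegion,
    GeneRecord,
    GenomeBuild,
    GenomicInterval,
    normalize_chrom,
)

SV_TYPES = (
    "insertion",
    "deletion",
    "duplication",
    "inversion",
    "intrachr_fusion",
    "translocation",
)

FUSION_CONFIDENCES = ("high", "medium", "low")


def load_genome(cytoband_path: str | Path) -> GenomeBuild:
    """Build a genome from a UCSC cytoBand-dialect file.

    Per-chromosome length is the maximum band end; the centromere is the
    union of that chromosome's ``acen``-stained bands. Chromosomes lacking
    an acen band raise an error naming the chromosome.
    """
    path = Path(cytoband_path)
    lengths: dict[str, int] = {}
    acen: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path.name}: malformed row at line {lineno}")
            chrom = normalize_chrom(parts[0])
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path.name}: malformed row at line {lineno}") from exc
            stain = parts[4]
            if chrom not in lengths:
                order.append(chrom)
                lengths[chrom] = 0
            lengths[chrom] = max(lengths[chrom], end)
            if stain == "acen":
                acen.setdefault(chrom, []).append((start, end))
    centromeres: dict[str, tuple[int, int]] = {}
    for chrom in order:
        if chrom not in acen:
            raise ValueError(f"no centromere: {chrom}")
        centromeres[chrom] = (
            min(s for s, _ in acen[chrom]),
            max(e for _, e in acen[chrom]),
        )
    return GenomeBuild(path.stem, [(c, lengths[c]) for c in order], centromeres)


def write_cytoband(build: GenomeBuild, path: str | Path) -> None:
    """Write a minimal cytoband rendering of a build (p/acen/q rows)."""
    rows = []
    for chrom in build.chrom_order:
        cs, ce = build.centromeres[chrom]
        if cs > 0:
            rows.append((chrom, 0, cs, f"{chrom[3:]}p11", "gneg"))
        rows.append((chrom, cs, ce, f"{chrom[3:]}cen", "acen"))
        if ce < build.lengths[chrom]:
            rows.append((chrom, ce, build.lengths[chrom], f"{chrom[3:]}q11", "gneg"))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# CNV segment tables


def read_cnv_segments(path: str | Path) -> pd.DataFrame:
    """Read a CNV segment table (sample_id, chrom, start, end, fract_cn, confidence)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "chrom", "start", "end", "fract_cn"], path)
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["start"] < 0).any() or (df["end"] < 0).any():
        raise ValueError(f"{path}: negative coordinates")
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: empty or inverted segments")
    if (df["fract_cn"] < 0).any():
        raise ValueError(f"{path}: negative fractional copy number")
    if "confidence" not in df.columns:
        df["confidence"] = 1.0
    return df


def write_cnv_segments(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "chrom", "start", "end", "fract_cn", "confidence"]
    df.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_seg_file(path: str | Path) -> pd.DataFrame:
    """Read a SEG file and convert log2 ratios to fractional copy number.

    seg.mean is log2(CN/2); fract_cn = 2 * 2**seg.mean. Returns the same
    schema as :func:`read_cnv_segments`.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["ID", "chrom", "loc.start", "loc.end", "seg.mean"], path)
    out = pd.DataFrame(
        {
            "sample_id": df["ID"].astype(str),
            "chrom": df["chrom"].map(normalize_chrom),
            "start": df["loc.start"].astype(int),
            "end": df["loc.end"].astype(int),
            "fract_cn": 2.0 * 2.0 ** df["seg.mean"].astype(float),
            "confidence": 1.0,
        }
    )
    if (out["start"] < 0).any():
        raise ValueError(f"{path}: negative coordinates")
    return out


def write_seg_file(df: pd.DataFrame, path: str | Path) -> None:
    """Write CNV segments in SEG dialect (seg.mean = log2(fract_cn/2))."""
    import numpy as np

    out = pd.DataFrame(
        {
            "ID": df["sample_id"],
            "chrom": df["chrom"],
            "loc.start": df["start"],
            "loc.end": df["end"],
            "num.mark": df.get("num_mark", pd.Series([50] * len(df))).values,
            "seg.mean": np.round(np.log2(df["fract_cn"].astype(float) / 2.0), 6),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SV tables


def read_sv_calls(path: str | Path) -> pd.DataFrame:
    """Read an SV call table (SMAP-inspired TSV).

    Columns: sv_id, sample_id, type, chrom1, pos1, chrom2, pos2, size_bp,
    confidence, control_af (empty allowed -> NaN).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sv_id": str, "sample_id": str})
    _require_columns(
        df,
        ["sv_id", "sample_id", "type", "chrom1", "pos1", "chrom2", "pos2", "size_bp", "confidence"],
        path,
    )
    bad = set(df["type"]) - set(SV_TYPES)
    if bad:
        raise ValueError(
            f"{path}: unknown SV type(s) {sorted(bad)}; allowed: {list(SV_TYPES)}"
        )
    df["chrom1"] = df["chrom1"].map(normalize_chrom)
    df["chrom2"] = df["chrom2"].map(normalize_chrom)
    for col in ("pos1", "pos2", "size_bp"):
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative {col}")
    if "control_af" not in df.columns:
        df["control_af"] = float("nan")
    af = df["control_af"].dropna()
    if ((af < 0) | (af > 1)).any():
        raise ValueError(f"{path}: control_af outside [0,1]")
    return df


def write_sv_calls(df: pd.DataFrame, path: str | Path) -> None:
    cols = [
        "sv_id", "sample_id", "type", "chrom1", "pos1", "chrom2", "pos2",
        "size_bp", "confidence", "control_af",
    ]
    extra = [c for c in df.columns if c not in cols]
    df.loc[:, cols + extra].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fusion tables


def read_fusion_calls(path: str | Path) -> pd.DataFrame:
    """Read an Arriba-style fusion table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(
        df, ["sample_id", "gene1", "gene2", "chrom1", "pos1", "chrom2", "pos2", "confidence"], path
    )
    bad = set(df["confidence"]) - set(FUSION_CONFIDENCES)
    if bad:
        raise ValueError(
            f"{path}: unknown confidence {sorted(bad)}; allowed: {list(FUSION_CONFIDENCES)}"
        )
    df["chrom1"] = df["chrom1"].map(normalize_chrom)
    df["chrom2"] = df["chrom2"].map(normalize_chrom)
    if "reading_frame" not in df.columns:
        df["reading_frame"] = "."
    return df


def write_fusion_calls(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "gene1", "gene2", "chrom1", "pos1", "chrom2", "pos2", "confidence", "reading_frame"]
    extra = [c for c in df.columns if c not in cols]
    df.loc[:, cols + extra].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Catalogs and gene models


def read_catalog(path: str | Path, source: str = "control-db") -> list[CatalogRegion]:
    """Read a BED3+af polymorphic-region catalog."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "af"])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CatalogRegion(
                GenomicInterval(normalize_chrom(row.chrom), int(row.start), int(row.end)),
                float(row.af),
                source,
            )
        )
    return out


def write_catalog(regions: Sequence[CatalogRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.allele_frequency}\n"
            )


def read_gene_model(path: str | Path) -> list[GeneRecord]:
    """Read a BED12-like gene model with a trailing cancer_census 0/1 column.

    Columns: chrom, start, end, name, score, strand, thickStart, thickEnd,
    rgb, blockCount, blockSizes, blockStarts, cancer_census.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 13:
                raise ValueError(f"{path}: malformed gene row at line {lineno}")
            chrom = normalize_chrom(p[0])
            start, end = int(p[1]), int(p[2])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            genes.append(
                GeneRecord(
                    symbol=p[3],
                    interval=GenomicInterval(chrom, start, end),
                    strand=p[5],
                    exons=exons,
                    cancer_census=bool(int(p[12])),
                )
            )
    return genes


def write_gene_model(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            sizes = ",".join(str(ex.length) for ex in g.exons)
            offsets = ",".join(str(ex.start - iv.start) for ex in g.exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            iv.chrom, iv.start, iv.end, g.symbol, 0, g.strand,
                            iv.start, iv.end, "0,0,0", len(g.exons), sizes, offsets,
                            int(g.cancer_census),
                        ],
                    )
                )
                + "\n"
            )


def write_bed(records: Sequence[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write simple BED4 rows (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
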