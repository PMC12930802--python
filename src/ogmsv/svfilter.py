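"""Somatic SV filtering cascade.

Stages, applied in order to an SV call table (pandas DataFrame in the
`io.read_sv_calls` schema):

1. common-SV removal — keep calls with control-database allele frequency
   <= 1% (absent AF means never seen in controls and is kept);
2. polymorphic-catalog exclusion — CNV-type SVs (deletion/duplication)
   reciprocally overlapping (>= 0.5) a catalog region of AF > 1% are
   removed; insertions/inversions are removed when both breakpoints fall
   inside one such region; translocations are never removed here;
3. germline subtraction against a matched-normal call-set, or — without a
   normal — translocation-class events are presumed somatic and the rest
   left undetermined;
4. gene / cancer-census / exonic annotation;
5. cross-sample recurrence clustering and per-type tallies.

Every stage is conservative: |input| = |retained| + |removed|, and the
filter_state column only moves forward (raw -> rare -> rare_nonpolymorphic
-> somatic/germline/presumed_somatic/undetermined).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import CatalogRegion, GeneRecord, GenomicInterval

CNV_TYPES = frozenset({"deletion", "duplication"})
BREAKPOINT_TYPES = frozenset({"insertion", "inversion"})
FUSION_CLASS_TYPES = frozenset({"intrachr_fusion", "translocation"})


@dataclass(frozen=True)
class CascadeConfig:
    """Tolerances of the cascade; defaults recorded in run metadata."""

    af_threshold: float = 0.01
    polymorphic_af: float = 0.01
    polymorphic_reciprocal: float = 0.5
    germline_reciprocal: float = 0.5
    germline_breakpoint_bp: int = 10_000
    germline_insertion_size_tol: float = 0.30
    germline_translocation_bp: int = 50_000
    flank_bp: int = 1_000
    recurrence_window_bp: int = 1_000_000
    recurrence_min_samples: int = 2


DEFAULT_CASCADE = CascadeConfig()


def _sv_interval(row) -> Optional[GenomicInterval]:
    """Genomic footprint of a CNV-type or inversion SV; None for others."""
    if row.chrom1 != row.chrom2:
        return None
    lo, hi = sorted((int(row.pos1), int(row.pos2)))
    if hi == lo:
        hi = lo + 1
    return GenomicInterval(row.chrom1, lo, hi)


def filter_common(
    svs: pd.DataFrame, af_threshold: float = DEFAULT_CASCADE.af_threshold
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split SVs into (rare, common) by control-database allele frequency.

    Rare = control_af <= threshold; an absent AF counts as 0 (never seen in
    controls). Rare rows get filter_state 'rare'.
    """
    af = svs["control_af"].fillna(0.0)
    if ((af < 0) | (af > 1)).any():
        raise ValueError("control_af outside [0,1]")
    keep = af <= af_threshold
    rare = svs[keep].copy()
    rare["filter_state"] = "rare"
    common = svs[~keep].copy()
    common["filter_state"] = "common"
    return rare, common


def filter_polymorphic(
    svs: pd.DataFrame,
    catalogs: Sequence[CatalogRegion],
    cfg: CascadeConfig = DEFAULT_CASCADE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove SVs explained by known polymorphic regions (catalog AF > 1%).

    Deletions/duplications: reciprocal overlap >= 0.5 with one region.
    Insertions/inversions: both breakpoints inside one region.
    Translocations/intrachromosomal fusions: never removed here.
    """
    hot = [c for c in catalogs if c.allele_frequency > cfg.polymorphic_af]
    removed_mask = np.zeros(len(svs), dtype=bool)
    for k, row in enumerate(svs.itertuples(index=False)):
        if row.type in CNV_TYPES:
            iv = _sv_interval(row)
            if iv is None:
                continue
            for region in hot:
                if iv.reciprocal_overlap(region.interval) >= cfg.polymorphic_reciprocal:
                    removed_mask[k] = True
                    break
        elif row.type in BREAKPOINT_TYPES:
            for region in hot:
                if region.interval.contains_point(row.chrom1, int(row.pos1)) and \
                   region.interval.contains_point(row.chrom2, int(row.pos2)):
                    removed_mask[k] = True
                    break
    retained = svs[~removed_mask].copy()
    retained["filter_state"] = "rare_nonpolymorphic"
    removed = svs[removed_mask].copy()
    removed["filter_state"] = "polymorphic"
    return retained, removed


def _breakpoints_match(row_t, row_b, tol_bp: int) -> bool:
    """Both partner breakpoints within tol_bp, in either orientation."""
    def close(c1, p1, c2, p2):
        return c1 == c2 and abs(int(p1) - int(p2)) <= tol_bp

    fwd = close(row_t.chrom1, row_t.pos1, row_b.chrom1, row_b.pos1) and \
        close(row_t.chrom2, row_t.pos2, row_b.chrom2, row_b.pos2)
    rev = close(row_t.chrom1, row_t.pos1, row_b.chrom2, row_b.pos2) and \
        close(row_t.chrom2, row_t.pos2, row_b.chrom1, row_b.pos1)
    return fwd or rev


def _germline_match(row_t, row_b, cfg: CascadeConfig) -> bool:
    if row_t.type != row_b.type:
        return False
    t = row_t.type
    if t in ("deletion", "duplication", "inversion"):
        iv_t, iv_b = _sv_interval(row_t), _sv_interval(row_b)
        if iv_t is not None and iv_b is not None and \
           iv_t.reciprocal_overlap(iv_b) >= cfg.germline_reciprocal:
            return True
        return _breakpoints_match(row_t, row_b, cfg.germline_breakpoint_bp)
    if t == "insertion":
        if not (row_t.chrom1 == row_b.chrom1 and
                abs(int(row_t.pos1) - int(row_b.pos1)) <= cfg.germline_breakpoint_bp):
            return False
        size_t, size_b = float(row_t.size_bp), float(row_b.size_bp)
        if max(size_t, size_b) == 0:
            return True
        return abs(size_t - size_b) / max(size_t, size_b) <= cfg.germline_insertion_size_tol
    # translocations / intrachromosomal fusions
    return _breakpoints_match(row_t, row_b, cfg.germline_translocation_bp)


def subtract_germline(
    tumor: pd.DataFrame,
    blood: pd.DataFrame,
    cfg: CascadeConfig = DEFAULT_CASCADE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition tumor SVs into (somatic, germline) by matched-normal lookup."""
    t_patients = set(tumor["sample_id"].str.rstrip("tb")) if len(tumor) else set()
    b_patients = set(blood["sample_id"].str.rstrip("tb")) if len(blood) else set()
    if t_patients and b_patients and t_patients != b_patients:
        raise ValueError(
            f"patient mismatch between tumor {sorted(t_patients)} and blood {sorted(b_patients)}"
        )
    blood_rows = list(blood.itertuples(index=False))
    is_germline = np.zeros(len(tumor), dtype=bool)
    for k, row_t in enumerate(tumor.itertuples(index=False)):
        for row_b in blood_rows:
            if _germline_match(row_t, row_b, cfg):
                is_germline[k] = True
                break
    somatic = tumor[~is_germline].copy()
    somatic["filter_state"] = "somatic"
    germline = tumor[is_germline].copy()
    germline["filter_state"] = "germline"
    return somatic, germline


def infer_somatic_unmatched(svs: pd.DataFrame) -> pd.DataFrame:
    """Without a matched normal, translocation-class events are presumed
    somatic (they are essentially absent from constitutional genomes);
    other types cannot be resolved and are flagged undetermined."""
    out = svs.copy()
    out["filter_state"] = np.where(
        out["type"].isin(FUSION_CLASS_TYPES), "presumed_somatic", "undetermined"
    )
    return out


def annotate_genes(
    svs: pd.DataFrame,
    genes: Sequence[GeneRecord],
    cfg: CascadeConfig = DEFAULT_CASCADE,
) -> pd.DataFrame:
    """Annotate each SV with overlapped genes, census and exonic flags.

    CNV-type SVs are intersected over their full genomic footprint;
    breakpoint-class SVs over +/- flank_bp around each breakpoint.
    """
    gene_syms: list[str] = []
    census_flags: list[bool] = []
    exonic_flags: list[bool] = []
    intronic_flags: list[bool] = []
    for row in svs.itertuples(index=False):
        if row.type in CNV_TYPES:
            probes = [_sv_interval(row)]
        else:
            probes = []
            for chrom, pos in ((row.chrom1, int(row.pos1)), (row.chrom2, int(row.pos2))):
                lo = max(0, pos - cfg.flank_bp)
                probes.append(GenomicInterval(chrom, lo, pos + cfg.flank_bp))
        hit_genes: list[str] = []
        census = exonic = False
        any_gene = False
        for g in genes:
            if any(p is not None and p.overlaps(g.interval) for p in probes):
                any_gene = True
                if g.symbol not in hit_genes:
                    hit_genes.append(g.symbol)
                census = census or g.cancer_census
                if any(
                    p is not None and p.overlaps(ex) for p in probes for ex in g.exons
                ):
                    exonic = True
        gene_syms.append(",".join(hit_genes))
        census_flags.append(census)
        exonic_flags.append(exonic)
        intronic_flags.append(any_gene and not exonic)
    out = svs.copy()
    out["genes"] = gene_syms
    out["cancer_census"] = census_flags
    out["exonic"] = exonic_flags
    out["intronic_only"] = intronic_flags
    return out


@dataclass
class RecurrentRegion:
    interval: GenomicInterval
    sv_ids: list[str]
    samples: set[str]
    dominant_gene: str

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def find_recurrent(
    svs: pd.DataFrame, cfg: CascadeConfig = DEFAULT_CASCADE
) -> list[RecurrentRegion]:
    """Cluster SV loci across samples; report regions hit in >= 2 samples.

    Single-linkage clustering of breakpoint1 positions per chromosome at
    the window distance; the dominant gene is the most frequent annotated
    gene among members (lexicographically smallest on ties).
    """
    regions: list[RecurrentRegion] = []
    if svs.empty:
        return regions
    has_genes = "genes" in svs.columns
    for chrom, sub in svs.groupby("chrom1", sort=True):
        sub = sub.sort_values(["pos1", "sv_id"])
        clusters: list[list] = []
        current: list = []
        prev_pos = None
        for row in sub.itertuples(index=False):
            if prev_pos is not None and int(row.pos1) - prev_pos > cfg.recurrence_window_bp:
                clusters.append(current)
                current = []
            current.append(row)
            prev_pos = int(row.pos1)
        if current:
            clusters.append(current)
        for members in clusters:
            samples = {m.sample_id for m in members}
            if len(samples) < cfg.recurrence_min_samples:
                continue
            lo = min(int(m.pos1) for m in members)
            hi = max(int(m.pos1) for m in members) + 1
            gene_counts: dict[str, int] = {}
            if has_genes:
                for m in members:
                    for g in str(m.genes).split(","):
                        if g and g != "nan":
                            gene_counts[g] = gene_counts.get(g, 0) + 1
            dominant = (
                min(
                    (g for g, n in gene_counts.items() if n == max(gene_counts.values())),
                )
                if gene_counts
                else ""
            )
            regions.append(
                RecurrentRegion(
                    GenomicInterval(chrom, lo, hi),
                    sorted(m.sv_id for m in members),
                    samples,
                    dominant,
                )
            )
    return regions


def tally(svs: pd.DataFrame, groups: Optional[dict[str, str]] = None) -> pd.DataFrame:
    """Counts and fractions of SVs by type; optional per-group mean +/- SD.

    Fractions sum to 1 over the supplied set (all zeros when empty).
    """
    from .io import SV_TYPES

    counts = {t: int((svs["type"] == t).sum()) for t in SV_TYPES} if len(svs) else {
        t: 0 for t in SV_TYPES
    }
    total = sum(counts.values())
    rows = []
    for t in SV_TYPES:
        row = {
            "type": t,
            "count": counts[t],
            "fraction": counts[t] / total if total else 0.0,
        }
        if groups is not None and len(svs):
            per_sample = (
                svs.assign(group=svs["sample_id"].map(groups))
                .groupby(["group", "sample_id"])
                .apply(lambda d, t=t: (d["type"] == t).sum(), include_groups=False)
            )
            for grp in sorted(set(groups.values())):
                vals = per_sample.loc[grp] if grp in per_sample.index.get_level_values(0) else pd.Series(dtype=float)
                row[f"{grp}_mean"] = float(vals.mean()) if len(vals) else 0.0
                row[f"{grp}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
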