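"""Cross-validation of DNA-level SVs against RNA-level fusion calls.

A somatic SV whose two breakpoints land in two distinct genes nominates a
candidate gene pair; RNA fusion calls carry the same gene pairs (with 5'/3'
orientation, which is ignored for matching because DNA breakpoints are
unoriented at the gene level). Event types are derived from breakpoint
geometry and gene strands, mirroring how RNA fusion callers categorize
their calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genome import GeneRecord, GenomicInterval
from .svfilter import CNV_TYPES


@dataclass(frozen=True)
class GenePairCandidate:
    sv_id: str
    sample_id: str
    sv_type: str
    genes: frozenset[str]  # one symbol when a breakpoint is intergenic

    @property
    def is_pair(self) -> bool:
        return len(self.genes) == 2


def _gene_at(
    genes: Sequence[GeneRecord], chrom: str, pos: int, flank_bp: int
) -> Optional[GeneRecord]:
    # a gene containing the breakpoint beats a flank-only neighbour
    nearby = None
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        if g.interval.contains_point(chrom, pos):
            return g
        if nearby is None and g.interval.start - flank_bp <= pos < g.interval.end + flank_bp:
            nearby = g
    return nearby


def sv_gene_pairs(
    svs: pd.DataFrame,
    genes: Sequence[GeneRecord],
    flank_bp: int = 10_000,
) -> list[GenePairCandidate]:
    """Candidate fusion gene pairs from annotated somatic SVs.

    Two distinct genes at the breakpoints (+/- flank) yield an unordered
    pair; one genic plus one intergenic breakpoint yields a one-gene
    record; a fully intragenic or fully intergenic SV yields nothing.
    """
    out: list[GenePairCandidate] = []
    for row in svs.itertuples(index=False):
        g1 = _gene_at(genes, row.chrom1, int(row.pos1), flank_bp)
        g2 = _gene_at(genes, row.chrom2, int(row.pos2), flank_bp)
        if g1 is not None and g2 is not None:
            if g1.symbol == g2.symbol:
                continue  # both breakpoints inside one gene: no fusion pair
            out.append(
                GenePairCandidate(row.sv_id, row.sample_id, row.type, frozenset({g1.symbol, g2.symbol}))
            )
        elif g1 is not None or g2 is not None:
            sym = (g1 or g2).symbol
            out.append(GenePairCandidate(row.sv_id, row.sample_id, row.type, frozenset({sym})))
    return out


def classify_fusion_event(
    bp5: tuple[str, int],
    bp3: tuple[str, int],
    strand5: str,
    strand3: str,
) -> str:
    """Infer the DNA event type behind a fusion transcript.

    Different chromosomes: translocation. Same chromosome with discordant
    strands: inversion. Concordant strands: a deletion joins the
    transcriptionally-upstream 5' gene to the downstream 3' gene (for plus
    strands, 5' breakpoint genomically before the 3' one; mirrored for
    minus strands); the opposite order implies a tandem duplication.
    """
    for s in (strand5, strand3):
        if s not in ("+", "-"):
            raise ValueError(f"unknown strand: {s!r}")
    (c5, p5), (c3, p3) = bp5, bp3
    if c5 != c3:
        return "translocation"
    if strand5 != strand3:
        return "inversion"
    if strand5 == "+":
        return "deletion" if p5 < p3 else "duplication"
    return "deletion" if p5 > p3 else "duplication"


# how a DNA SV type may present at RNA level
_TYPE_MAP = {
    "deletion": {"deletion"},
    "duplication": {"duplication"},
    "inversion": {"inversion"},
    "translocation": {"translocation"},
    "intrachr_fusion": {"deletion", "duplication", "inversion"},
}


@dataclass
class XvalRecord:
    sample_id: str
    genes: frozenset[str]
    dna_sv_ids: list[str]
    rna_fusion_ids: list[str]
    status: str  # both | dna_only | rna_only
    type_consistent: bool


def classify_fusion_table(
    fusions: pd.DataFrame, genes: Sequence[GeneRecord]
) -> pd.DataFrame:
    """Add an event_type column to an RNA fusion table."""
    by_symbol = {g.symbol: g for g in genes}
    types = []
    for row in fusions.itertuples(index=False):
        g5, g3 = by_symbol.get(row.gene1), by_symbol.get(row.gene2)
        if g5 is None or g3 is None:
            types.append("translocation" if row.chrom1 != row.chrom2 else "unknown")
            continue
        types.append(
            classify_fusion_event(
                (row.chrom1, int(row.pos1)), (row.chrom2, int(row.pos2)),
                g5.strand, g3.strand,
            )
        )
    out = fusions.copy()
    out["event_type"] = types
    return out


def cross_validate(
    dna_pairs: Sequence[GenePairCandidate],
    rna_fusions: pd.DataFrame,
    min_confidence: str = "high",
) -> list[XvalRecord]:
    """Match DNA gene pairs to RNA fusions by unordered gene-pair identity.

    Confidence gating keeps RNA calls at or above min_confidence (ordering
    high > medium > low). Every DNA pair and every retained RNA fusion
    lands in exactly one record; one-gene DNA records can only be dna_only.
    """
    rank = {"high": 2, "medium": 1, "low": 0}
    if min_confidence not in rank:
        raise ValueError(f"unknown confidence: {min_confidence!r}")
    rna = rna_fusions[rna_fusions["confidence"].map(rank) >= rank[min_confidence]]
    dna_samples = {p.sample_id for p in dna_pairs}
    rna_samples = set(rna["sample_id"]) if len(rna) else set()
    # per-sample matching; cross-sample ids are an error only if disjoint inputs claim same pair
    records: list[XvalRecord] = []
    rna_index: dict[tuple[str, frozenset[str]], list[int]] = {}
    rna_types: dict[int, str] = {}
    for idx, row in enumerate(rna.itertuples(index=False)):
        key = (row.sample_id, frozenset({row.gene1, row.gene2}))
        rna_index.setdefault(key, []).append(idx)
        rna_types[idx] = getattr(row, "event_type", "unknown")
    used_rna: set[tuple[str, frozenset[str]]] = set()
    # group DNA candidates by (sample, pair)
    dna_index: dict[tuple[str, frozenset[str]], list[GenePairCandidate]] = {}
    for p in dna_pairs:
        dna_index.setdefault((p.sample_id, p.genes), []).append(p)
    for (sample_id, pair), cands in sorted(
        dna_index.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))
    ):
        rna_hits = rna_index.get((sample_id, pair), []) if len(pair) == 2 else []
        if rna_hits:
            used_rna.add((sample_id, pair))
            consistent = any(
                rna_types[i] in _TYPE_MAP.get(c.sv_type, set())
                for i in rna_hits
                for c in cands
            )
            records.append(
                XvalRecord(sample_id, pair, [c.sv_id for c in cands],
                           [f"rna{i}" for i in rna_hits], "both", consistent)
            )
        else:
            records.append(
                XvalRecord(sample_id, pair, [c.sv_id for c in cands], [], "dna_only", False)
            )
    for key, hits in sorted(rna_index.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))):
        if key in used_rna:
            continue
        sample_id, pair = key
        records.append(
            XvalRecord(sample_id, pair, [], [f"rna{i}" for i in hits], "rna_only", False)
        )
    return records


def xval_table(records: Sequence[XvalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "genes": "::".join(sorted(r.genes)),
                "dna_sv_ids": ",".join(r.dna_sv_ids),
                "rna_fusion_ids": ",".join(r.rna_fusion_ids),
                "status": r.status,
                "type_consistent": r.type_consistent,
            }
            for r in records
        ]
    )
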