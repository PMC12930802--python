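"""Genome metadata and interval algebra.

Coordinates are 0-based half-open throughout: an interval printed as
``chr13:90,684,670-92,265,557`` has length ``end - start`` = 1,580,887 bp.
Interval *sets* are plain lists of :class:`GenomicInterval`; set algebra
requires (and defensively applies) normalization — per-chromosome sorting
and merging of overlapping or touching intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len_a, overlap/len_b); 0 when disjoint."""
        ov = self.intersection_bp(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a half-open interval (end - start)."""
    return iv.length


@dataclass(frozen=True)
class CatalogRegion:
    """A population-polymorphic region with its control allele frequency."""

    interval: GenomicInterval
    allele_frequency: float
    source: str = "control-db"

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError(f"allele frequency outside [0,1]: {self.allele_frequency}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with exon structure and a cancer-census membership flag."""

    symbol: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]
    cancer_census: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -: {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"exon on wrong chromosome in {self.symbol}")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon outside gene body in {self.symbol}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.symbol}")
            prev_end = ex.end


class GenomeBuild:
    """Ordered chromosomes with lengths, centromeres, and derived arms."""

    def __init__(
        self,
        name: str,
        chromosomes: Sequence[tuple[str, int]],
        centromeres: Mapping[str, tuple[int, int]],
    ) -> None:
        self.name = name
        self.chrom_order = [c for c, _ in chromosomes]
        if len(set(self.chrom_order)) != len(self.chrom_order):
            raise ValueError("duplicate chromosome names")
        self.lengths = dict(chromosomes)
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}")
        self.centromeres: dict[str, tuple[int, int]] = {}
        for chrom in self.chrom_order:
            if chrom not in centromeres:
                raise ValueError(f"no centromere: {chrom}")
            cs, ce = centromeres[chrom]
            if not (0 <= cs < ce <= self.lengths[chrom]):
                raise ValueError(f"centromere outside chromosome: {chrom}")
            self.centromeres[chrom] = (cs, ce)

    def chrom_length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def arm(self, chrom: str, which: str) -> GenomicInterval:
        """The p arm [0, cen_start) or q arm [cen_end, length)."""
        cs, ce = self.centromeres[chrom]
        if which == "p":
            return GenomicInterval(chrom, 0, cs)
        if which == "q":
            return GenomicInterval(chrom, ce, self.lengths[chrom])
        raise ValueError(f"arm must be 'p' or 'q': {which!r}")

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.lengths:
            raise ValueError(f"unknown chromosome: {iv.chrom}")
        if iv.end > self.lengths[iv.chrom]:
            raise ValueError(
                f"interval beyond chromosome end: {iv.chrom}:{iv.start}-{iv.end}"
            )

    def __repr__(self) -> str:
        return f"GenomeBuild({self.name!r}, {len(self.chrom_order)} chromosomes)"


def normalize_chrom(name: str) -> str:
    """Canonical 'chr'-prefixed chromosome name."""
    name = str(name).strip()
    if not name.lower().startswith("chr"):
        return "chr" + name
    return "chr" + name[3:]


def is_normalized(ivs: Sequence[GenomicInterval]) -> bool:
    by_chrom: dict[str, GenomicInterval] = {}
    seen_chroms: list[str] = []
    for iv in ivs:
        prev = by_chrom.get(iv.chrom)
        if prev is None:
            if iv.chrom in seen_chroms:
                return False
            seen_chroms.append(iv.chrom)
        elif iv.start <= prev.end:  # overlap or touching => not merged
            return False
        elif iv.start < prev.start:
            return False
        by_chrom[iv.chrom] = iv
    return True


def normalize(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def total_span(ivs: Sequence[GenomicInterval]) -> int:
    """Total bases covered by a normalized interval set."""
    return sum(iv.length for iv in normalize(ivs))


def intersect_total(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Total overlapping bases between two interval sets (commutative).

    Inputs are expected normalized; unnormalized inputs are normalized
    defensively with a warning.
    """
    if not is_normalized(a) or not is_normalized(b):
        warnings.warn("intersect_total: normalizing unnormalized input", stacklevel=2)
        a, b = normalize(a), normalize(b)
    total = 0
    # two-pointer sweep per chromosome
    from collections import defaultdict

    a_by: dict[str, list[GenomicInterval]] = defaultdict(list)
    b_by: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in a:
        a_by[iv.chrom].append(iv)
    for iv in b:
        b_by[iv.chrom].append(iv)
    for chrom in set(a_by) & set(b_by):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            total += xs[i].intersection_bp(ys[j])
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return total


def subtract(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-set difference a \\ b, returned normalized."""
    a, b = normalize(a), normalize(b)
    from collections import defaultdict

    b_by: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in b:
        b_by[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for iv in a:
        cur = iv.start
        for cut in b_by.get(iv.chrom, []):
            if cut.end <= cur or cut.start >= iv.end:
                continue
            if cut.start > cur:
                out.append(GenomicInterval(iv.chrom, cur, cut.start))
            cur = max(cur, cut.end)
            if cur >= iv.end:
                break
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, cur, iv.end))
    return out
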