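"""Ground-truthed synthetic cohort generator.

Emulates the data structure of a medulloblastoma OGM study at desk scale:
five molecular groups (WNT, SHH-infant, SHH-child, Group 3, Group 4) with
their characteristic copy-number archetypes (monosomy 6, isochromosome
17q, trisomies, focal amplifications, complex alternating segments),
purity-attenuated fractional CN rendered by two platforms at different
resolution, germline/somatic SV sets with control-database allele
frequencies, and RNA fusion evidence for a subset of genic somatic SVs.

The default genome is a 24-chromosome scaled-down genome (human chromosome
proportions at 1/10 scale, centromeres placed near mid-chromosome so that
arm-scoped events fall inside the arm-call window); a 6-chromosome toy
genome is provided for brute-force oracle work. Observed fractional CN
follows the standard linear purity mixture 2 + p*(CN_true - 2) plus
truncated Gaussian noise. All randomness flows from one numpy Generator,
so a fixed seed reproduces byte-identical file sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .fusion import classify_fusion_event
from .genome import CatalogRegion, GeneRecord, GenomeBuild, GenomicInterval

# ---------------------------------------------------------------------------
# Genomes

_HUMAN_MBP = {
    "chr1": 249, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 182,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51, "chrX": 156, "chrY": 57,
}


def scaled_genome(scale: int = 10) -> GenomeBuild:
    """Human chromosome proportions at 1/scale, mid-chromosome centromeres."""
    chroms = [(c, mbp * 1_000_000 // scale) for c, mbp in _HUMAN_MBP.items()]
    cens = {c: (int(0.46 * length), int(0.48 * length)) for c, length in chroms}
    return GenomeBuild(f"synthetic-1to{scale}", chroms, cens)


def toy_genome() -> GenomeBuild:
    """Six chromosomes of 10-60 Mbp for fast exhaustive checks."""
    lengths = [60, 50, 40, 30, 20, 10]
    chroms = [(f"chr{i+1}", mbp * 1_000_000) for i, mbp in enumerate(lengths)]
    cens = {c: (int(0.45 * length), int(0.50 * length)) for c, length in chroms}
    return GenomeBuild("toy6", chroms, cens)


def synthetic_genes(
    genome: GenomeBuild, rng: np.random.Generator, n_genes: int = 200
) -> list[GeneRecord]:
    """Scatter non-overlapping genes over the genome.

    Includes two fixed landmark genes: NRX1L, a large multi-intron gene on
    the chr2 p arm (an NRXN1-like recurrence target), and GPC5L inside the
    chr13 focal-amplification locus. Roughly 5% of genes carry the
    cancer-census flag (the landmarks always do).
    """
    genes: list[GeneRecord] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_order}

    def _add(symbol, chrom, start, end, strand, n_exons, census):
        span = end - start
        bounds = np.sort(rng.choice(np.arange(1, span // 100), size=2 * n_exons, replace=False)) * 100
        exons = tuple(
            GenomicInterval(chrom, start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
            for i in range(n_exons)
        )
        genes.append(GeneRecord(symbol, GenomicInterval(chrom, start, end), strand, exons, census))
        occupied[chrom].append((start, end))

    # NRX1L gets a fixed exon layout with a 249 kbp second intron, the
    # landing zone for planted recurrent deletions
    nrx_start = genome.arm("chr2", "p").start + 200_000
    nrx_offsets = [0, 50_000] + [300_000 + 45_000 * i for i in range(18)]
    nrx_exons = tuple(
        GenomicInterval("chr2", nrx_start + off, nrx_start + off + 1_000)
        for off in nrx_offsets
    )
    genes.append(GeneRecord("NRX1L", GenomicInterval("chr2", nrx_start, nrx_start + 1_100_000),
                            "-", nrx_exons, True))
    occupied["chr2"].append((nrx_start, nrx_start + 1_100_000))
    amp = focal_amp_locus(genome)
    _add("GPC5L", amp.chrom, amp.start + 100_000, amp.start + 400_000, "+", 8, True)

    chrom_names = list(genome.chrom_order)
    lengths = np.array([genome.lengths[c] for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    made = 0
    while made < n_genes - 2:
        chrom = chrom_names[rng.choice(len(chrom_names), p=probs)]
        size = int(rng.integers(20_000, 200_000))
        start = int(rng.integers(0, genome.lengths[chrom] - size))
        if any(start < e and s < start + size for s, e in occupied[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        census = rng.random() < 0.05
        _add(f"G{made + 1:03d}", chrom, start, start + size, strand, int(rng.integers(2, 8)), census)
        made += 1
    return sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))


def focal_amp_locus(genome: GenomeBuild) -> GenomicInterval:
    """The fixed chr13 q-arm locus used for planted focal amplifications."""
    q = genome.arm("chr13", "q")
    start = q.start + (q.length // 3)
    return GenomicInterval("chr13", start, start + 600_000)


def synthetic_catalog(
    genome: GenomeBuild, rng: np.random.Generator, n_regions: int = 60
) -> list[CatalogRegion]:
    """Polymorphic-region catalog; half the regions exceed the 1% AF bar."""
    chrom_names = list(genome.chrom_order)
    lengths = np.array([genome.lengths[c] for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    for k in range(n_regions):
        chrom = chrom_names[rng.choice(len(chrom_names), p=probs)]
        size = int(rng.integers(20_000, 300_000))
        start = int(rng.integers(0, genome.lengths[chrom] - size))
        af = float(rng.uniform(0.02, 0.4)) if k % 2 == 0 else float(rng.uniform(0.0, 0.01))
        out.append(CatalogRegion(GenomicInterval(chrom, start, start + size), af, "synthetic-catalog"))
    return sorted(out, key=lambda r: (r.interval.chrom, r.interval.start))


# ---------------------------------------------------------------------------
# Archetypes and configuration


@dataclass(frozen=True)
class GroupArchetype:
    """Per-group CN archetype: fixed events, rates, and the altered-
    chromosome target the fill-in events aim for."""

    label: str
    fixed_whole: tuple[tuple[str, str, float], ...] = ()  # (chrom, direction, prob)
    joint_trisomy: tuple[str, ...] = ()  # chroms gained together
    joint_trisomy_prob: float = 0.0
    iso_prob: float = 0.0
    iso_chrom: str = "chr17"
    iso_fallback_trisomy: bool = False
    focal_amp_prob: float = 0.0
    focal_amp_cn: tuple[int, int] = (10, 20)
    complex_prob: float = 0.0
    recurrent_prob: float = 0.0
    target_altered: float = 2.0
    target_sd: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.joint_trisomy_prob, self.iso_prob, self.focal_amp_prob,
                  self.complex_prob, self.recurrent_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability outside [0,1] in archetype {self.label}: {p}")


# Study-condition archetypes: group sizes and CN patterns mirror the
# reported cohort (WNT 2.67+/-0.58 altered chromosomes with universal
# monosomy 6; SHH-infant 2.00+/-1.10 with occasional joint trisomy 2+3;
# SHH-child 6.80+/-3.49; Group 3 14.25+/-3.30 with i17q in 3/4 and a focal
# amplification case; Group 4 8.00+/-4.90 with i17q in 9/11 and trisomy 17
# otherwise; NRXN1-locus recurrence concentrated in Groups 3/4).
ARCHETYPES: dict[str, GroupArchetype] = {
    "WNT": GroupArchetype(
        "WNT",
        fixed_whole=(("chr6", "loss", 1.0), ("chrX", "loss", 1 / 3),
                     ("chr11", "loss", 1 / 3), ("chrY", "loss", 1 / 3)),
        target_altered=2.67, target_sd=0.58,
    ),
    "SHH_infant": GroupArchetype(
        "SHH_infant",
        joint_trisomy=("chr2", "chr3"), joint_trisomy_prob=1 / 3,
        target_altered=2.0, target_sd=1.1,
    ),
    "SHH_child": GroupArchetype(
        "SHH_child", complex_prob=0.3, target_altered=6.8, target_sd=3.49,
    ),
    "Group3": GroupArchetype(
        "Group3", iso_prob=0.75, focal_amp_prob=0.25, complex_prob=0.75,
        recurrent_prob=0.75, target_altered=14.25, target_sd=3.3,
    ),
    "Group4": GroupArchetype(
        "Group4", iso_prob=9 / 11, iso_fallback_trisomy=True, complex_prob=0.5,
        recurrent_prob=0.2, target_altered=8.0, target_sd=4.9,
    ),
}

DEFAULT_GROUP_SIZES = {"WNT": 3, "SHH_infant": 6, "SHH_child": 5, "Group3": 4, "Group4": 11}


@dataclass(frozen=True)
class PlatformParams:
    name: str
    boundary_jitter_sd: float  # Gaussian sd in bp
    min_segment_bp: int
    detection_floor_log2: float  # drop segments with |log2(cn/2)| below this


OGM_PLATFORM = PlatformParams("ogm", boundary_jitter_sd=2_000, min_segment_bp=500,
                              detection_floor_log2=0.0)
ARRAY_PLATFORM = PlatformParams("array", boundary_jitter_sd=50_000, min_segment_bp=50_000,
                                detection_floor_log2=0.1)


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: tuple[tuple[str, int], ...] = tuple(DEFAULT_GROUP_SIZES.items())
    purity_range: tuple[float, float] = (0.8, 1.0)
    noise_sd: float = 0.05
    n_sv_per_tumor: int = 60
    germline_fraction: float = 0.6
    common_share: float = 0.3  # share of germline SVs with control AF > 1%
    polymorphic_share: float = 0.2  # share of rare germline CNV-SVs placed in hot catalog regions
    genic_share: float = 0.5  # share of somatic SVs planted as gene-pair events
    fusion_fraction: float = 0.4  # share of eligible genic somatic SVs given RNA evidence
    matched_normal_count: int = 18
    germline_sv_jitter_bp: int = 0  # uniform +/- jitter between tumor and blood renderings
    ogm: PlatformParams = OGM_PLATFORM
    array: PlatformParams = ARRAY_PLATFORM
    n_genes: int = 200
    n_catalog: int = 60
    genome_scale: int = 10

    def __post_init__(self) -> None:
        for p in (self.germline_fraction, self.common_share, self.polymorphic_share,
                  self.genic_share, self.fusion_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability outside [0,1]: {p}")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity range must sit in (0,1]: {self.purity_range}")


DEFAULT_CONFIG = CohortConfig()


# ---------------------------------------------------------------------------
# Truth container


@dataclass
class CohortTruth:
    config: CohortConfig
    genome: GenomeBuild
    genes: list[GeneRecord]
    catalog: list[CatalogRegion]
    samples: pd.DataFrame  # sample_id, group, purity, matched_normal
    truth_cn: pd.DataFrame  # sample_id, chrom, start, end, true_cn, tag
    truth_sv: pd.DataFrame  # sv schema + origin, af_class, gene5, gene3
    cnv_ogm: pd.DataFrame
    cnv_array: pd.DataFrame
    sv_tumor: pd.DataFrame
    sv_blood: pd.DataFrame
    fusions: pd.DataFrame
    expression: pd.DataFrame  # gene x sample, log2(norm counts + 1)


# ---------------------------------------------------------------------------
# CN truth planting


def _plant_sample_cn(
    group: str, arche: GroupArchetype, genome: GenomeBuild, rng: np.random.Generator
) -> list[dict]:
    """Plant one sample's true integer-CN regions; one event per chromosome
    except complex chromosomes (alternating focal segments)."""
    regions: list[dict] = []
    used: set[str] = set()

    def whole(chrom, direction):
        cn = 1 if direction == "loss" else 3
        regions.append(dict(chrom=chrom, start=0, end=genome.lengths[chrom], true_cn=cn, tag="whole"))
        used.add(chrom)

    for chrom, direction, prob in arche.fixed_whole:
        if chrom not in used and rng.random() < prob:
            whole(chrom, direction)
    if arche.joint_trisomy and rng.random() < arche.joint_trisomy_prob:
        for chrom in arche.joint_trisomy:
            if chrom not in used:
                whole(chrom, "gain")
    if arche.iso_prob and rng.random() < arche.iso_prob:
        chrom = arche.iso_chrom
        p, q = genome.arm(chrom, "p"), genome.arm(chrom, "q")
        regions.append(dict(chrom=chrom, start=p.start, end=p.end, true_cn=1, tag="p_arm"))
        regions.append(dict(chrom=chrom, start=q.start, end=q.end, true_cn=3, tag="q_arm"))
        used.add(chrom)
    elif arche.iso_fallback_trisomy:
        whole(arche.iso_chrom, "gain")
    if arche.focal_amp_prob and rng.random() < arche.focal_amp_prob:
        locus = focal_amp_locus(genome)
        if locus.chrom not in used:
            cn = int(rng.integers(*arche.focal_amp_cn))
            regions.append(dict(chrom=locus.chrom, start=locus.start, end=locus.end,
                                true_cn=cn, tag="focal"))
            used.add(locus.chrom)
    if arche.complex_prob and rng.random() < arche.complex_prob:
        candidates = [c for c in genome.chrom_order[:12] if c not in used]
        if candidates:
            chrom = candidates[int(rng.integers(len(candidates)))]
            q = genome.arm(chrom, "q")
            seg = min(500_000, q.length // 8)
            gap = seg // 2
            pos = q.start + gap
            for cn in (3, 1, 3):
                regions.append(dict(chrom=chrom, start=pos, end=pos + seg, true_cn=cn, tag="complex"))
                pos += seg + gap
            used.add(chrom)
    # fill with random events up to the altered-chromosome target
    n_target = int(np.clip(round(rng.normal(arche.target_altered, arche.target_sd)),
                           0, len(genome.chrom_order)))
    free = [c for c in genome.chrom_order if c not in used]
    rng.shuffle(free)
    first_fill = True
    for chrom in free[: max(0, n_target - len(used))]:
        direction = "gain" if rng.random() < 0.5 else "loss"
        cn = 3 if direction == "gain" else 1
        kind = rng.random()
        if first_fill or kind < 0.55:
            first_fill = False
            regions.append(dict(chrom=chrom, start=0, end=genome.lengths[chrom], true_cn=cn, tag="whole"))
        elif kind < 0.80:
            which = "p" if rng.random() < 0.5 else "q"
            arm = genome.arm(chrom, which)
            regions.append(dict(chrom=chrom, start=arm.start, end=arm.end, true_cn=cn,
                                tag=f"{which}_arm"))
        else:
            max_size = min(2_500_000, int(0.25 * genome.lengths[chrom]))
            size = int(rng.integers(300_000, max(300_001, max_size)))
            start = int(rng.integers(0, genome.lengths[chrom] - size))
            focal_cn = cn if rng.random() < 0.7 else (0 if direction == "loss" else 5)
            regions.append(dict(chrom=chrom, start=start, end=start + size,
                                true_cn=focal_cn, tag="focal"))
        used.add(chrom)
    return regions


def expected_state(true_cn: int, purity: float) -> str:
    """CN state a noiseless rendering of this truth would classify to."""
    from .cnv import classify_cn

    return classify_cn(2.0 + purity * (true_cn - 2.0))


# ---------------------------------------------------------------------------
# Platform rendering


def render_cnv_platform(
    truth_cn: pd.DataFrame,
    samples: pd.DataFrame,
    genome: GenomeBuild,
    params: PlatformParams,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Render planted CN truth as a platform's segment table.

    Observed fract_cn = 2 + purity*(CN_true - 2) + N(0, noise_sd), truncated
    at 0. Segment boundaries receive Gaussian jitter (sd per platform) and
    are clipped to the chromosome and de-overlapped; segments shorter than
    the platform minimum or with |log2(cn/2)| below the platform detection
    floor are dropped (how a lower-resolution platform misses low-level
    gains).
    """
    purity = dict(zip(samples["sample_id"], samples["purity"]))
    rows = []
    for row in truth_cn.itertuples(index=False):
        p = purity[row.sample_id]
        obs = 2.0 + p * (row.true_cn - 2.0)
        if noise_sd > 0:
            obs += rng.normal(0.0, noise_sd)
        obs = max(obs, 0.0)
        start, end = int(row.start), int(row.end)
        if params.boundary_jitter_sd > 0:
            start += int(rng.normal(0, params.boundary_jitter_sd))
            end += int(rng.normal(0, params.boundary_jitter_sd))
        chrom_len = genome.lengths[row.chrom]
        start = max(0, min(start, chrom_len - 1))
        end = max(start + 1, min(end, chrom_len))
        if end - start < params.min_segment_bp:
            continue
        if params.detection_floor_log2 > 0:
            if obs <= 0 or abs(np.log2(max(obs, 1e-9) / 2.0)) < params.detection_floor_log2:
                continue
        rows.append(dict(sample_id=row.sample_id, chrom=row.chrom, start=start, end=end,
                         fract_cn=round(float(obs), 4), confidence=0.99))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "fract_cn", "confidence"])
    # de-overlap segments jittered into each other (later start trimmed)
    df = df.sort_values(["sample_id", "chrom", "start", "end"]).reset_index(drop=True)
    for i in range(1, len(df)):
        if (df.at[i, "sample_id"] == df.at[i - 1, "sample_id"]
                and df.at[i, "chrom"] == df.at[i - 1, "chrom"]
                and df.at[i, "start"] < df.at[i - 1, "end"]):
            df.at[i, "start"] = df.at[i - 1, "end"]
    df = df[df["end"] > df["start"]].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# SV truth planting


def _random_breakpoint(genome: GenomeBuild, rng: np.random.Generator, margin: int = 600_000):
    chroms = list(genome.chrom_order)
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
    chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
    pos = int(rng.integers(margin, genome.lengths[chrom] - margin))
    return chrom, pos


def _plant_sample_svs(
    sample_id: str,
    arche: GroupArchetype,
    genome: GenomeBuild,
    genes: Sequence[GeneRecord],
    hot_regions: Sequence[CatalogRegion],
    cfg: CohortConfig,
    rng: np.random.Generator,
    sv_counter: list[int],
) -> list[dict]:
    """Plant one tumor's SV truth rows (germline and somatic)."""
    from types import SimpleNamespace

    from .svfilter import DEFAULT_CASCADE, _germline_match

    rows: list[dict] = []
    n_total = cfg.n_sv_per_tumor
    n_germ = int(round(cfg.germline_fraction * n_total))
    n_som = n_total - n_germ

    def new_id():
        sv_counter[0] += 1
        return f"sv{sv_counter[0]:05d}"

    germline_ns: list[SimpleNamespace] = []

    def hot_conflict(row: dict) -> bool:
        """Would the polymorphic filter remove this SV?"""
        if row["type"] in ("deletion", "duplication"):
            lo, hi = sorted((row["pos1"], row["pos2"]))
            iv = GenomicInterval(row["chrom1"], lo, max(hi, lo + 1))
            return any(iv.reciprocal_overlap(r.interval) >= 0.5 for r in hot_regions)
        if row["type"] in ("insertion", "inversion"):
            return any(
                r.interval.contains_point(row["chrom1"], row["pos1"])
                and r.interval.contains_point(row["chrom2"], row["pos2"])
                for r in hot_regions
            )
        return False

    def germline_conflict(row: dict) -> bool:
        """Would germline subtraction mislabel this somatic SV?"""
        ns = SimpleNamespace(**row)
        return any(_germline_match(ns, g, DEFAULT_CASCADE) for g in germline_ns)

    def base_row(svtype, c1, p1, c2, p2, size):
        return dict(sv_id=new_id(), sample_id=sample_id, type=svtype,
                    chrom1=c1, pos1=int(p1), chrom2=c2, pos2=int(p2),
                    size_bp=int(size), confidence=round(float(rng.uniform(0.8, 1.0)), 3),
                    control_af=np.nan, origin="somatic", af_class="rare",
                    gene5="", gene3="")

    germ_types = ["deletion", "insertion", "duplication", "inversion"]
    germ_probs = [0.4, 0.3, 0.2, 0.1]
    for _ in range(n_germ):
        svtype = germ_types[rng.choice(4, p=germ_probs)]
        common = rng.random() < cfg.common_share
        in_poly = (not common) and svtype in ("deletion", "duplication") and \
            hot_regions and rng.random() < cfg.polymorphic_share
        if in_poly:
            region = hot_regions[int(rng.integers(len(hot_regions)))].interval
            size = max(1000, int(region.length * rng.uniform(0.7, 0.95)))
            start = region.start + int(rng.integers(0, max(1, region.length - size)))
            chrom, p1, p2 = region.chrom, start, start + size
            row = base_row(svtype, chrom, p1, chrom, p2, size)
        else:
            for _try in range(100):
                chrom, p1 = _random_breakpoint(genome, rng)
                size = int(rng.integers(5_000, 500_000)) if svtype != "insertion" else int(rng.integers(500, 10_000))
                p2 = p1 + (size if svtype != "insertion" else int(rng.integers(100, 1_000)))
                row = base_row(svtype, chrom, p1, chrom, p2, size)
                if not hot_conflict(row):
                    break
        row["origin"] = "germline"
        if common:
            row["control_af"] = round(float(rng.uniform(0.02, 0.5)), 4)
            row["af_class"] = "common"
        else:
            row["control_af"] = round(float(rng.uniform(0.0, 0.01)), 4) if rng.random() < 0.5 else np.nan
            row["af_class"] = "polymorphic" if in_poly else "rare"
        rows.append(row)
        from types import SimpleNamespace as _NS

        germline_ns.append(_NS(**{k: row[k] for k in
                                  ("type", "chrom1", "pos1", "chrom2", "pos2", "size_bp")}))

    # recurrence target: a deletion inside the NRX1L-like gene's intron span
    nrx = next(g for g in genes if g.symbol == "NRX1L")
    if arche.recurrent_prob and rng.random() < arche.recurrent_prob:
        # concentrate hits in a 150 kbp intron window so they cluster
        intron_lo = nrx.exons[1].end
        for _try in range(100):
            p1 = int(rng.integers(intron_lo, intron_lo + 150_000))
            size = int(rng.integers(5_000, 25_000))
            row = base_row("deletion", nrx.interval.chrom, p1, nrx.interval.chrom, p1 + size, size)
            if not hot_conflict(row) and not germline_conflict(row):
                break
        rows.append(row)
        n_som = max(0, n_som - 1)

    n_genic = int(round(cfg.genic_share * n_som))
    same_chrom_pairs: dict[str, list[GeneRecord]] = {}
    for g in genes:
        same_chrom_pairs.setdefault(g.interval.chrom, []).append(g)
    for _ in range(n_genic):
        if rng.random() < 0.3:  # interchromosomal pair
            g5, g3 = None, None
            for _try in range(50):
                a, b = (genes[i] for i in rng.choice(len(genes), size=2, replace=False))
                if a.interval.chrom != b.interval.chrom:
                    g5, g3 = a, b
                    break
        else:
            g5 = g3 = None
            for _try in range(50):
                chrom = genome.chrom_order[int(rng.integers(len(genome.chrom_order)))]
                cands = same_chrom_pairs.get(chrom, [])
                if len(cands) >= 2:
                    i, j = rng.choice(len(cands), size=2, replace=False)
                    g5, g3 = cands[int(i)], cands[int(j)]
                    break
        if g5 is None:
            continue
        for _try in range(100):
            bp5 = (g5.interval.chrom, int(rng.integers(g5.interval.start, g5.interval.end)))
            bp3 = (g3.interval.chrom, int(rng.integers(g3.interval.start, g3.interval.end)))
            event = classify_fusion_event(bp5, bp3, g5.strand, g3.strand)
            if event == "translocation":
                svtype, size = "translocation", 0
                c1, p1, c2, p2 = bp5[0], bp5[1], bp3[0], bp3[1]
            else:
                svtype = event
                c1 = c2 = bp5[0]
                p1, p2 = sorted((bp5[1], bp3[1]))
                size = p2 - p1
            row = base_row(svtype, c1, p1, c2, p2, size)
            if not hot_conflict(row) and not germline_conflict(row):
                break
        row["gene5"], row["gene3"] = g5.symbol, g3.symbol
        rows.append(row)

    som_types = ["deletion", "insertion", "duplication", "inversion", "intrachr_fusion", "translocation"]
    som_probs = [0.35, 0.25, 0.15, 0.10, 0.05, 0.10]
    for _ in range(n_som - n_genic):
        svtype = som_types[rng.choice(6, p=som_probs)]
        for _try in range(100):
            chrom, p1 = _random_breakpoint(genome, rng)
            if svtype == "translocation":
                c2, p2 = _random_breakpoint(genome, rng)
                while c2 == chrom:
                    c2, p2 = _random_breakpoint(genome, rng)
                row = base_row(svtype, chrom, p1, c2, p2, 0)
            elif svtype == "intrachr_fusion":
                p2 = min(p1 + int(rng.integers(1_000_000, 3_000_000)), genome.lengths[chrom] - 1)
                row = base_row(svtype, chrom, p1, chrom, p2, 0)
            else:
                size = int(rng.integers(5_000, 500_000)) if svtype != "insertion" else int(rng.integers(500, 10_000))
                p2 = p1 + (size if svtype != "insertion" else int(rng.integers(100, 1_000)))
                p2 = min(p2, genome.lengths[chrom] - 1)
                row = base_row(svtype, chrom, p1, chrom, p2, size)
            if not hot_conflict(row) and not germline_conflict(row):
                break
        rows.append(row)
    return rows


def plant_fusion_evidence(
    truth_sv: pd.DataFrame,
    genes: Sequence[GeneRecord],
    fraction: float,
    seed: int,
) -> pd.DataFrame:
    """Give the stated fraction of eligible genic somatic SVs an RNA record.

    Eligible = somatic with two distinct annotated partner genes. Exactly
    round(fraction * n_eligible) records are emitted (deterministic for a
    fixed seed), with breakpoints copied from the SV and confidence high.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction outside [0,1]: {fraction}")
    rng = np.random.default_rng(seed)
    by_symbol = {g.symbol: g for g in genes}
    eligible = truth_sv[
        (truth_sv["origin"] == "somatic")
        & (truth_sv["gene5"] != "")
        & (truth_sv["gene3"] != "")
        & (truth_sv["gene5"] != truth_sv["gene3"])
    ].reset_index(drop=True)
    n_pick = int(round(fraction * len(eligible)))
    picked_idx = sorted(rng.choice(len(eligible), size=n_pick, replace=False)) if n_pick else []
    rows = []
    for i in picked_idx:
        sv = eligible.iloc[int(i)]
        g5, g3 = by_symbol[sv["gene5"]], by_symbol[sv["gene3"]]
        # orient breakpoints back to the 5'/3' genes
        if g5.interval.contains_point(sv["chrom1"], int(sv["pos1"])):
            bp5, bp3 = (sv["chrom1"], int(sv["pos1"])), (sv["chrom2"], int(sv["pos2"]))
        else:
            bp5, bp3 = (sv["chrom2"], int(sv["pos2"])), (sv["chrom1"], int(sv["pos1"]))
        rows.append(dict(sample_id=sv["sample_id"], gene1=g5.symbol, gene2=g3.symbol,
                         chrom1=bp5[0], pos1=bp5[1], chrom2=bp3[0], pos2=bp3[1],
                         confidence="high", reading_frame=".", source_sv_id=sv["sv_id"]))
    return pd.DataFrame(rows, columns=["sample_id", "gene1", "gene2", "chrom1", "pos1",
                                       "chrom2", "pos2", "confidence", "reading_frame",
                                       "source_sv_id"])


# ---------------------------------------------------------------------------
# Cohort assembly


def generate_cohort(
    config: CohortConfig = DEFAULT_CONFIG,
    seed: int = 0,
    outdir: Optional[str | Path] = None,
) -> CohortTruth:
    """Generate a full ground-truthed cohort; optionally write all files.

    Deterministic for a fixed (config, seed): re-running reproduces
    byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    genome = scaled_genome(config.genome_scale)
    genes = synthetic_genes(genome, rng, config.n_genes)
    catalog = synthetic_catalog(genome, rng, config.n_catalog)
    hot = [c for c in catalog if c.allele_frequency > 0.01]

    sample_rows = []
    k = 0
    for group, n in config.group_sizes:
        for _ in range(n):
            k += 1
            sample_rows.append(dict(
                sample_id=f"S{k:02d}t", patient_id=f"S{k:02d}", group=group,
                purity=round(float(rng.uniform(*config.purity_range)), 3),
            ))
    samples = pd.DataFrame(sample_rows)
    matched = set(samples["patient_id"].iloc[: config.matched_normal_count])
    samples["matched_normal"] = samples["patient_id"].isin(matched)

    cn_rows = []
    sv_rows = []
    sv_counter = [0]
    for srow in samples.itertuples(index=False):
        arche = ARCHETYPES[srow.group]
        for r in _plant_sample_cn(srow.group, arche, genome, rng):
            r["sample_id"] = srow.sample_id
            cn_rows.append(r)
        sv_rows.extend(
            _plant_sample_svs(srow.sample_id, arche, genome, genes, hot, config, rng, sv_counter)
        )
    truth_cn = pd.DataFrame(cn_rows)[["sample_id", "chrom", "start", "end", "true_cn", "tag"]]
    truth_sv = pd.DataFrame(sv_rows)

    cnv_ogm = render_cnv_platform(truth_cn, samples, genome, config.ogm, config.noise_sd, rng)
    cnv_array = render_cnv_platform(truth_cn, samples, genome, config.array, config.noise_sd, rng)

    sv_cols = ["sv_id", "sample_id", "type", "chrom1", "pos1", "chrom2", "pos2",
               "size_bp", "confidence", "control_af"]
    sv_tumor = truth_sv[sv_cols].copy()
    blood_rows = []
    j = config.germline_sv_jitter_bp
    for row in truth_sv[truth_sv["origin"] == "germline"].itertuples(index=False):
        patient = row.sample_id[:-1]
        if patient not in matched:
            continue
        d1 = int(rng.integers(-j, j + 1)) if j else 0
        d2 = int(rng.integers(-j, j + 1)) if j else 0
        blood_rows.append(dict(
            sv_id=row.sv_id + "b", sample_id=patient + "b", type=row.type,
            chrom1=row.chrom1, pos1=max(0, row.pos1 + d1),
            chrom2=row.chrom2, pos2=max(0, row.pos2 + d2),
            size_bp=row.size_bp, confidence=row.confidence, control_af=row.control_af,
        ))
    sv_blood = pd.DataFrame(blood_rows, columns=sv_cols)

    fusions = plant_fusion_evidence(truth_sv, genes, config.fusion_fraction,
                                    seed=int(rng.integers(0, 2**31 - 1)))

    # expression corroboration table for census genes: amplified samples poke out
    census_syms = [g.symbol for g in genes if g.cancer_census]
    amp_locus = focal_amp_locus(genome)
    amp_samples = set(
        truth_cn[(truth_cn["tag"] == "focal") & (truth_cn["true_cn"] > 4)
                 & (truth_cn["chrom"] == amp_locus.chrom)
                 & (truth_cn["start"] <= amp_locus.start)
                 ]["sample_id"]
    )
    expr = {}
    for sym in census_syms:
        base = rng.normal(5.0, 0.3, size=len(samples))
        vals = dict(zip(samples["sample_id"], np.round(base, 3)))
        if sym == "GPC5L":
            for sid in amp_samples:
                vals[sid] = round(float(rng.uniform(11.0, 13.0)), 3)
        expr[sym] = vals
    expression = pd.DataFrame(expr).T
    expression.index.name = "gene"

    truth = CohortTruth(config, genome, genes, catalog, samples, truth_cn, truth_sv,
                        cnv_ogm, cnv_array, sv_tumor, sv_blood, fusions, expression)
    if outdir is not None:
        write_cohort(truth, outdir)
    return truth


def write_cohort(truth: CohortTruth, outdir: str | Path) -> None:
    """Write the full rendered file set plus machine-readable truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_cytoband(truth.genome, out / "cytoband.txt")
    gio.write_gene_model(truth.genes, out / "genes.bed")
    gio.write_catalog(truth.catalog, out / "catalog.bed")
    gio.write_cnv_segments(truth.cnv_ogm, out / "cnv_ogm.tsv")
    gio.write_seg_file(truth.cnv_array, out / "cnv_array.seg")
    gio.write_sv_calls(truth.sv_tumor, out / "sv_tumor.tsv")
    gio.write_sv_calls(truth.sv_blood, out / "sv_blood.tsv")
    gio.write_fusion_calls(truth.fusions, out / "fusions.tsv")
    truth.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    truth.truth_cn.to_csv(out / "truth_cn.tsv", sep="\t", index=False)
    truth.truth_sv.to_csv(out / "truth_sv.tsv", sep="\t", index=False)
    truth.expression.to_csv(out / "expression.tsv", sep="\t")
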