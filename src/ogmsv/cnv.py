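"""Fractional-copy-number segment classification and aneuploidy calling.

A bulk tumor segment carries a fractional copy number (fractCN): a
non-integer estimate reflecting tumor purity and subclonality around the
diploid baseline of 2. Segments are binned into five states by fixed
thresholds; whole-chromosome and arm-level aneuploidies are called from the
fraction of the chromosome covered by directionally-altered bases
("fractional CN size"); chromosomes carrying both gains and losses, or
several alternations of non-balanced states, are flagged complex, and a
gain on one arm concomitant with a loss on the other suggests an
isochromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .genome import GenomeBuild, GenomicInterval, normalize, total_span

STATES = ("homozygous_deletion", "hemizygous_deletion", "balanced", "gain", "amplification")
GAIN_STATES = frozenset({"gain", "amplification"})
LOSS_STATES = frozenset({"hemizygous_deletion", "homozygous_deletion"})


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for CN-state, size-class and aneuploidy calling.

    Defaults are the operational cut-offs for OGM fractional CN:
    1.800 <= CN <= 2.200 balanced; 2.200 < CN <= 3.500 gain; CN > 3.500
    amplification; CN < 1.800 hemizygous deletion; CN < 0.800 homozygous
    deletion. Focal means < 3 Mbp. Whole-chromosome aneuploidy requires
    altered fraction >= 0.630 of the chromosome, an arm event >= 0.315.
    """

    balanced_low: float = 1.800
    balanced_high: float = 2.200
    gain_high: float = 3.500
    homo_low: float = 0.800
    focal_max_bp: int = 3_000_000
    whole_chrom_frac: float = 0.630
    arm_frac: float = 0.315
    arm_concentration: float = 0.90  # share of altered bases that must sit on one arm
    arm_frac_denominator: str = "chromosome"  # or "arm"

    def __post_init__(self) -> None:
        if not (self.homo_low < self.balanced_low < self.balanced_high < self.gain_high):
            raise ValueError("CN thresholds must be strictly ordered")
        if not (0 < self.arm_frac < self.whole_chrom_frac < 1):
            raise ValueError("aneuploidy fractions must satisfy 0 < arm < whole < 1")


DEFAULT_CONFIG = ClassificationConfig()


def classify_cn(fract_cn: float, cfg: ClassificationConfig = DEFAULT_CONFIG) -> str:
    """Assign a CN state to a fractional copy number.

    Boundary behaviour follows the defining inequalities: 1.800 and 2.200
    are balanced, 3.500 is a gain, 0.800 is a hemizygous deletion.
    """
    if fract_cn < 0:
        raise ValueError(f"negative fractional CN: {fract_cn}")
    if fract_cn < cfg.homo_low:
        return "homozygous_deletion"
    if fract_cn < cfg.balanced_low:
        return "hemizygous_deletion"
    if fract_cn <= cfg.balanced_high:
        return "balanced"
    if fract_cn <= cfg.gain_high:
        return "gain"
    return "amplification"


def size_class(iv: GenomicInterval, cfg: ClassificationConfig = DEFAULT_CONFIG) -> str:
    """Focal (< 3 Mbp) versus partial (> 3 Mbp); exactly 3 Mbp is focal."""
    return "focal" if iv.length <= cfg.focal_max_bp else "partial"


@dataclass(frozen=True)
class AneuploidyCall:
    chrom: str
    scope: str  # whole_chromosome | p_arm | q_arm
    direction: str  # gain | loss
    fraction: float  # altered bases / chromosome length


def _direction_of(state: str) -> str | None:
    if state in GAIN_STATES:
        return "gain"
    if state in LOSS_STATES:
        return "loss"
    return None


def call_aneuploidy(
    segments: pd.DataFrame,
    genome: GenomeBuild,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> list[AneuploidyCall]:
    """Call whole-chromosome/arm aneuploidies from one chromosome's segments.

    ``segments`` needs columns chrom/start/end/state and must be
    non-overlapping and single-chromosome. Per direction, the altered
    fraction is the summed length of that direction's segments divided by
    the chromosome length; >= whole_chrom_frac yields a whole-chromosome
    call, else >= arm_frac with >= 90% of the altered bases on one arm
    yields that arm's call.
    """
    if segments.empty:
        return []
    chroms = segments["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError("call_aneuploidy expects segments from a single chromosome")
    chrom = chroms[0]
    seg_sorted = segments.sort_values("start")
    if (seg_sorted["start"].values[1:] < seg_sorted["end"].values[:-1]).any():
        raise ValueError(f"overlapping segments on {chrom}")
    chrom_len = genome.chrom_length(chrom)
    calls: list[AneuploidyCall] = []
    for direction, states in (("gain", GAIN_STATES), ("loss", LOSS_STATES)):
        sub = seg_sorted[seg_sorted["state"].isin(states)]
        if sub.empty:
            continue
        ivs = [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
        altered = total_span(ivs)
        fraction = altered / chrom_len
        if fraction >= cfg.whole_chrom_frac:
            calls.append(AneuploidyCall(chrom, "whole_chromosome", direction, fraction))
            continue
        arm_threshold = cfg.arm_frac
        for which in ("p", "q"):
            arm = genome.arm(chrom, which)
            on_arm = sum(iv.intersection_bp(arm) for iv in ivs)
            if cfg.arm_frac_denominator == "arm":
                frac_for_threshold = on_arm / arm.length if arm.length else 0.0
            else:
                frac_for_threshold = fraction
            if (
                frac_for_threshold >= arm_threshold
                and altered > 0
                and on_arm / altered >= cfg.arm_concentration
            ):
                calls.append(AneuploidyCall(chrom, f"{which}_arm", direction, fraction))
                break
    return calls


def detect_complex(states: list[str]) -> bool:
    """Complex signature: gains and losses coexisting on one chromosome, or
    >= 3 alternations among consecutive non-balanced states (e.g. the
    alternating fractCN pattern 2.223 / 1.646 / 2.834)."""
    nonbal = [s for s in states if s != "balanced"]
    dirs = {_direction_of(s) for s in nonbal}
    if "gain" in dirs and "loss" in dirs:
        return True
    alternations = sum(1 for a, b in zip(nonbal, nonbal[1:]) if a != b)
    return alternations >= 3


def detect_isochromosome(calls: list[AneuploidyCall]) -> bool:
    """True iff one arm carries a gain call and the other arm a loss call."""
    arm_dirs = {(c.scope, c.direction) for c in calls if c.scope in ("p_arm", "q_arm")}
    return (
        (("p_arm", "gain") in arm_dirs and ("q_arm", "loss") in arm_dirs)
        or (("p_arm", "loss") in arm_dirs and ("q_arm", "gain") in arm_dirs)
    )


@dataclass
class CnvProfile:
    """Per-sample classified CNV profile."""

    sample_id: str
    platform: str
    segments: pd.DataFrame  # classified, non-balanced rows flagged in 'state'
    aneuploidies: list[AneuploidyCall]
    complex_chroms: set[str]
    isochromosome_chroms: set[str]
    prevalence: int  # chromosomes with >= 1 non-balanced segment

    @property
    def cnv_calls(self) -> pd.DataFrame:
        """The CNV call-set: balanced segments excluded."""
        return self.segments[self.segments["state"] != "balanced"]


def classify_segments(
    segments: pd.DataFrame, cfg: ClassificationConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Add state and size_class columns to a CNV segment table."""
    out = segments.copy()
    out["state"] = out["fract_cn"].map(lambda v: classify_cn(v, cfg))
    out["size_class"] = [
        size_class(GenomicInterval(c, int(s), int(e)), cfg)
        for c, s, e in zip(out["chrom"], out["start"], out["end"])
    ]
    return out


def build_profile(
    segments: pd.DataFrame,
    genome: GenomeBuild,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
    platform: str = "ogm",
) -> CnvProfile:
    """Classify one sample's segments and derive all per-chromosome calls."""
    samples = segments["sample_id"].unique()
    if len(samples) > 1:
        raise ValueError("build_profile expects a single sample's segments")
    sample_id = samples[0] if len(samples) else ""
    classified = classify_segments(segments, cfg)
    aneuploidies: list[AneuploidyCall] = []
    complex_chroms: set[str] = set()
    iso_chroms: set[str] = set()
    affected = 0
    for chrom, sub in classified.groupby("chrom", sort=False):
        nonbal = sub[sub["state"] != "balanced"]
        if nonbal.empty:
            continue
        affected += 1
        calls = call_aneuploidy(sub, genome, cfg)
        aneuploidies.extend(calls)
        states_in_order = list(sub.sort_values("start")["state"])
        if detect_complex(states_in_order):
            complex_chroms.add(chrom)
        if detect_isochromosome(calls):
            iso_chroms.add(chrom)
    return CnvProfile(
        sample_id=sample_id,
        platform=platform,
        segments=classified,
        aneuploidies=aneuploidies,
        complex_chroms=complex_chroms,
        isochromosome_chroms=iso_chroms,
        prevalence=affected,
    )


def profiles_by_sample(
    segments: pd.DataFrame,
    genome: GenomeBuild,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
    platform: str = "ogm",
) -> dict[str, CnvProfile]:
    return {
        sid: build_profile(sub, genome, cfg, platform)
        for sid, sub in segments.groupby("sample_id", sort=True)
    }


def oncoprint_matrix(profiles: dict[str, CnvProfile], genome: GenomeBuild) -> pd.DataFrame:
    """Sample x chromosome category matrix for oncoprint-style tools.

    Categories (one per cell, most specific wins): isochromosome > complex >
    whole-chromosome gain/loss > arm gain/loss > focal/partial alteration >
    balanced.
    """
    rows = {}
    for sid, prof in sorted(profiles.items()):
        by_chrom: dict[str, str] = {c: "balanced" for c in genome.chrom_order}
        nonbal = prof.cnv_calls
        for chrom in nonbal["chrom"].unique():
            klass = "focal" if (nonbal[nonbal["chrom"] == chrom]["size_class"] == "focal").all() else "partial"
            by_chrom[chrom] = f"{klass}_alteration"
        for call in prof.aneuploidies:
            label = {
                ("whole_chromosome", "gain"): "trisomy_like_gain",
                ("whole_chromosome", "loss"): "monosomy_like_loss",
                ("p_arm", "gain"): "p_arm_gain",
                ("p_arm", "loss"): "p_arm_loss",
                ("q_arm", "gain"): "q_arm_gain",
                ("q_arm", "loss"): "q_arm_loss",
            }[(call.scope, call.direction)]
            by_chrom[call.chrom] = label
        for chrom in prof.complex_chroms:
            by_chrom[chrom] = "complex"
        for chrom in prof.isochromosome_chroms:
            by_chrom[chrom] = "isochromosome"
        rows[sid] = by_chrom
    return pd.DataFrame.from_dict(rows, orient="index")[genome.chrom_order]
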