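"""Cross-platform CNV concordance via the Sorensen (Dice) coefficient.

Each sample's classified profile is reduced to a gain track and a loss
track (normalized base sets). Two platforms' tracks are compared with the
Sorensen coefficient S = 2|A∩B| / (|A| + |B|); samples where both platforms
report a fully balanced genome leave S undefined and are excluded from
cohort summaries. Event-level concordance counts merged same-direction
events matched by greedy reciprocal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .cnv import GAIN_STATES, LOSS_STATES, CnvProfile
from .genome import GenomicInterval, intersect_total, normalize, total_span


@dataclass
class StatusTrack:
    sample_id: str
    platform: str
    gain: list[GenomicInterval]
    loss: list[GenomicInterval]

    @property
    def empty(self) -> bool:
        return not self.gain and not self.loss


def status_track(profile: CnvProfile) -> StatusTrack:
    """Reduce a classified profile to normalized gain/loss base sets."""
    calls = profile.cnv_calls
    gain = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e, st in zip(calls["chrom"], calls["start"], calls["end"], calls["state"])
        if st in GAIN_STATES
    ]
    loss = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e, st in zip(calls["chrom"], calls["start"], calls["end"], calls["state"])
        if st in LOSS_STATES
    ]
    return StatusTrack(profile.sample_id, profile.platform, normalize(gain), normalize(loss))


def sorensen(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> Optional[float]:
    """S = 2|a∩b| / (|a| + |b|); None when both sets are empty."""
    sa, sb = total_span(a), total_span(b)
    if sa + sb == 0:
        return None
    return 2.0 * intersect_total(a, b) / (sa + sb)


@dataclass
class ConcordanceResult:
    sample_id: str
    sorensen_gain: Optional[float]
    sorensen_loss: Optional[float]
    sorensen_combined: Optional[float]
    events_both: int
    events_only_a: int
    events_only_b: int
    excluded: bool
    exclusion_reason: str = ""


def match_events(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_reciprocal: float = 0.5,
) -> tuple[int, int, int]:
    """Greedy best-first 1:1 matching of merged events by reciprocal overlap.

    Returns (both, only_a, only_b). Symmetric: swapping inputs swaps the
    only-counts and preserves the both-count.
    """
    a, b = normalize(a), normalize(b)
    pairs = []
    for i, iv_a in enumerate(a):
        for j, iv_b in enumerate(b):
            ro = iv_a.reciprocal_overlap(iv_b)
            if ro >= min_reciprocal:
                pairs.append((ro, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    both = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        both += 1
    return both, len(a) - both, len(b) - both


def sample_concordance(
    track_a: StatusTrack, track_b: StatusTrack, min_reciprocal: float = 0.5
) -> ConcordanceResult:
    """Per-sample two-platform concordance.

    The combined coefficient is the span-weighted mean of the defined
    per-direction coefficients (weights |a|+|b| per direction), so it
    reduces to the single defined value when only one direction has events.
    """
    if track_a.sample_id != track_b.sample_id:
        raise ValueError(
            f"sample mismatch: {track_a.sample_id} vs {track_b.sample_id}"
        )
    if track_a.empty and track_b.empty:
        return ConcordanceResult(
            track_a.sample_id, None, None, None, 0, 0, 0,
            excluded=True, exclusion_reason="balanced genome on both platforms",
        )
    s_parts: list[tuple[float, float]] = []  # (S, weight)
    s_gain = sorensen(track_a.gain, track_b.gain)
    s_loss = sorensen(track_a.loss, track_b.loss)
    if s_gain is not None:
        s_parts.append((s_gain, total_span(track_a.gain) + total_span(track_b.gain)))
    if s_loss is not None:
        s_parts.append((s_loss, total_span(track_a.loss) + total_span(track_b.loss)))
    combined = sum(s * w for s, w in s_parts) / sum(w for _, w in s_parts)
    bg, oa_g, ob_g = match_events(track_a.gain, track_b.gain, min_reciprocal)
    bl, oa_l, ob_l = match_events(track_a.loss, track_b.loss, min_reciprocal)
    return ConcordanceResult(
        track_a.sample_id, s_gain, s_loss, combined,
        events_both=bg + bl, events_only_a=oa_g + oa_l, events_only_b=ob_g + ob_l,
        excluded=False,
    )


def combined_sorensen(track_a: StatusTrack, track_b: StatusTrack) -> Optional[float]:
    """Span-weighted combined Sorensen between any two tracks (cross-sample OK)."""
    parts = []
    for ga, gb in ((track_a.gain, track_b.gain), (track_a.loss, track_b.loss)):
        s = sorensen(ga, gb)
        if s is not None:
            parts.append((s, total_span(ga) + total_span(gb)))
    if not parts:
        return None
    return sum(s * w for s, w in parts) / sum(w for _, w in parts)


@dataclass
class CohortConcordance:
    overall: float  # fraction of union events detected by both platforms
    per_sample: pd.DataFrame
    matrix: pd.DataFrame  # combined Sorensen across all tracks
    leaf_order: list[str]
    mode: str = "event"


def cohort_concordance(
    results: Sequence[ConcordanceResult],
    tracks: Optional[Sequence[StatusTrack]] = None,
) -> CohortConcordance:
    """Cohort-level concordance over non-excluded samples.

    overall = (sum of both-platform events) / (sum of union events); the
    matrix and clustering cover every supplied track (all samples x both
    platforms), with average linkage on distance 1 − S and deterministic
    lexicographic tie-breaking via pre-sorted labels.
    """
    live = [r for r in results if not r.excluded]
    if not live:
        raise ValueError("all samples excluded: no concordance to compute")
    both = sum(r.events_both for r in live)
    union = sum(r.events_both + r.events_only_a + r.events_only_b for r in live)
    overall = both / union if union else 1.0
    per_sample = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "sorensen_gain": r.sorensen_gain,
                "sorensen_loss": r.sorensen_loss,
                "sorensen_combined": r.sorensen_combined,
                "events_both": r.events_both,
                "events_only_a": r.events_only_a,
                "events_only_b": r.events_only_b,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in sorted(results, key=lambda r: r.sample_id)
        ]
    )
    matrix = pd.DataFrame()
    leaf_order: list[str] = []
    if tracks:
        labeled = sorted(tracks, key=lambda t: (t.sample_id, t.platform))
        labels = [f"{t.sample_id}:{t.platform}" for t in labeled]
        n = len(labeled)
        m = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s = combined_sorensen(labeled[i], labeled[j])
                m[i, j] = m[j, i] = 0.0 if s is None else s
        matrix = pd.DataFrame(m, index=labels, columns=labels)
        if n > 1:
            dist = squareform(1.0 - m, checks=False)
            order = leaves_list(average(dist))
            leaf_order = [labels[i] for i in order]
        else:
            leaf_order = labels
    return CohortConcordance(overall, per_sample, matrix, leaf_order)
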