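"""Brute-force reference implementations used only by tests.

Everything here works on per-base boolean vectors or quadratic all-pairs
scans over tiny toy genomes, independent of the package's sweep/merge
implementations.
"""

from __future__ import annotations

import numpy as np


def per_base_mask(intervals, lengths):
    """chrom -> boolean coverage vector for a list of (chrom, start, end)."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    for chrom, start, end in intervals:
        masks[chrom][start:end] = True
    return masks


def intersect_bp_oracle(a, b, lengths):
    ma, mb = per_base_mask(a, lengths), per_base_mask(b, lengths)
    return sum(int((ma[c] & mb[c]).sum()) for c in lengths)


def dice_oracle(a, b, lengths):
    """Per-base Dice 2TP/(2TP+FP+FN); None when both sets empty."""
    ma, mb = per_base_mask(a, lengths), per_base_mask(b, lengths)
    tp = sum(int((ma[c] & mb[c]).sum()) for c in lengths)
    na = sum(int(ma[c].sum()) for c in lengths)
    nb = sum(int(mb[c].sum()) for c in lengths)
    if na + nb == 0:
        return None
    return 2.0 * tp / (na + nb)


def aneuploidy_oracle(segments, chrom_len, cen_start, cen_end,
                      whole_frac=0.630, arm_frac=0.315, concentration=0.90):
    """Per-base tally of one chromosome's (start, end, direction) segments.

    direction in {'gain', 'loss'}; returns a set of (scope, direction).
    """
    calls = set()
    for direction in ("gain", "loss"):
        mask = np.zeros(chrom_len, dtype=bool)
        for start, end, d in segments:
            if d == direction:
                mask[start:end] = True
        altered = int(mask.sum())
        if altered == 0:
            continue
        fraction = altered / chrom_len
        if fraction >= whole_frac:
            calls.add(("whole_chromosome", direction))
            continue
        if fraction >= arm_frac:
            on_p = int(mask[:cen_start].sum())
            on_q = int(mask[cen_end:].sum())
            if on_p / altered >= concentration:
                calls.add(("p_arm", direction))
            elif on_q / altered >= concentration:
                calls.add(("q_arm", direction))
    return calls


def _reciprocal(a_start, a_end, b_start, b_end):
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    if ov == 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def polymorphic_removed_oracle(svs, catalog, af=0.01, reciprocal=0.5):
    """All-pairs scan; svs are dict rows, catalog is (chrom,start,end,af)."""
    removed = set()
    hot = [c for c in catalog if c[3] > af]
    for sv in svs:
        if sv["type"] in ("deletion", "duplication") and sv["chrom1"] == sv["chrom2"]:
            lo, hi = sorted((sv["pos1"], sv["pos2"]))
            hi = max(hi, lo + 1)
            for c, s, e, _ in hot:
                if c == sv["chrom1"] and _reciprocal(lo, hi, s, e) >= reciprocal:
                    removed.add(sv["sv_id"])
                    break
        elif sv["type"] in ("insertion", "inversion"):
            for c, s, e, _ in hot:
                if (c == sv["chrom1"] and s <= sv["pos1"] < e
                        and c == sv["chrom2"] and s <= sv["pos2"] < e):
                    removed.add(sv["sv_id"])
                    break
    return removed


def germline_ids_oracle(tumor, blood, reciprocal=0.5, bp_tol=10_000,
                        ins_size_tol=0.30, tra_tol=50_000):
    """Quadratic scan marking tumor SVs matched by a blood SV of same type."""

    def bp_close(a, b, tol):
        fwd = (a["chrom1"] == b["chrom1"] and abs(a["pos1"] - b["pos1"]) <= tol
               and a["chrom2"] == b["chrom2"] and abs(a["pos2"] - b["pos2"]) <= tol)
        rev = (a["chrom1"] == b["chrom2"] and abs(a["pos1"] - b["pos2"]) <= tol
               and a["chrom2"] == b["chrom1"] and abs(a["pos2"] - b["pos1"]) <= tol)
        return fwd or rev

    germline = set()
    for t in tumor:
        for b in blood:
            if t["type"] != b["type"]:
                continue
            hit = False
            if t["type"] in ("deletion", "duplication", "inversion"):
                lo_t, hi_t = sorted((t["pos1"], t["pos2"]))
                lo_b, hi_b = sorted((b["pos1"], b["pos2"]))
                if t["chrom1"] == b["chrom1"] and \
                        _reciprocal(lo_t, max(hi_t, lo_t + 1), lo_b, max(hi_b, lo_b + 1)) >= reciprocal:
                    hit = True
                elif bp_close(t, b, bp_tol):
                    hit = True
            elif t["type"] == "insertion":
                if t["chrom1"] == b["chrom1"] and abs(t["pos1"] - b["pos1"]) <= bp_tol:
                    hi = max(t["size_bp"], b["size_bp"])
                    hit = hi == 0 or abs(t["size_bp"] - b["size_bp"]) / hi <= ins_size_tol
            else:
                hit = bp_close(t, b, tra_tol)
            if hit:
                germline.add(t["sv_id"])
                break
    return germline


def recurrence_oracle(rows, window, min_samples=2):
    """Single-linkage 1-D clustering by repeated merging (quadratic).

    rows: (sv_id, sample_id, chrom, pos). Returns a set of frozensets of
    member sv_ids for clusters with enough distinct samples.
    """
    clusters = [
        {"ids": {r[0]}, "samples": {r[1]}, "chrom": r[2], "pos": [r[3]]}
        for r in rows
    ]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                if a["chrom"] != b["chrom"]:
                    continue
                if min(abs(x - y) for x in a["pos"] for y in b["pos"]) <= window:
                    a["ids"] |= b["ids"]
                    a["samples"] |= b["samples"]
                    a["pos"] += b["pos"]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return {
        frozenset(c["ids"]) for c in clusters if len(c["samples"]) >= min_samples
    }
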