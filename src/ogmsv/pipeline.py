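"""End-to-end orchestration over a rendered cohort directory.

Expects the file layout written by :func:`ogmsv.simulate.write_cohort`
(equally producible by hand for real call-sets): cytoband.txt, genes.bed,
catalog.bed, cnv_ogm.tsv, cnv_array.seg, sv_tumor.tsv, sv_blood.tsv,
fusions.tsv, samples.tsv, optionally expression.tsv. Produces the report
set as TSVs plus a run-metadata YAML recording every tolerance used.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as gio
from .cnv import ClassificationConfig, CnvProfile, oncoprint_matrix, profiles_by_sample
from .concordance import cohort_concordance, sample_concordance, status_track
from .fusion import classify_fusion_table, cross_validate, sv_gene_pairs, xval_table
from .stats import expression_corroboration, group_stats
from .svfilter import (
    CascadeConfig,
    annotate_genes,
    filter_common,
    filter_polymorphic,
    find_recurrent,
    infer_somatic_unmatched,
    subtract_germline,
    tally,
)

log = logging.getLogger("ogmsv")


@dataclass
class RunConfig:
    indir: str
    outdir: str
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    concordance_min_reciprocal: float = 0.5
    fusion_min_confidence: str = "high"
    fusion_flank_bp: int = 10_000
    alpha: float = 0.05
    seed: int = 0


def _aneuploidy_table(profiles: dict[str, CnvProfile]) -> pd.DataFrame:
    rows = []
    for sid, prof in sorted(profiles.items()):
        for c in prof.aneuploidies:
            rows.append(dict(sample_id=sid, chrom=c.chrom, scope=c.scope,
                             direction=c.direction, fraction=round(c.fraction, 4),
                             isochromosome=c.chrom in prof.isochromosome_chroms))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "scope", "direction",
                                       "fraction", "isochromosome"])


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns a dict of in-memory results and writes reports."""
    t0 = time.time()
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    meta: dict = {
        "classification": asdict(cfg.classification),
        "cascade": asdict(cfg.cascade),
        "concordance_min_reciprocal": cfg.concordance_min_reciprocal,
        "concordance_mode": "event",
        "fusion_min_confidence": cfg.fusion_min_confidence,
        "alpha": cfg.alpha,
        "seed": cfg.seed,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t = time.time()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            meta["stages"][name] = {"seconds": round(time.time() - t, 3)}
            log.info("stage %s done in %.2fs", name, time.time() - t)
            return out
        return wrap

    genome = stage("load_genome")(lambda: gio.load_genome(indir / "cytoband.txt"))
    genes = stage("load_genes")(lambda: gio.read_gene_model(indir / "genes.bed"))
    catalog = stage("load_catalog")(lambda: gio.read_catalog(indir / "catalog.bed"))
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", dtype={"sample_id": str})
    groups = dict(zip(samples["sample_id"], samples["group"]))

    # --- CNV classification, both platforms -------------------------------
    ogm_segments = gio.read_cnv_segments(indir / "cnv_ogm.tsv")
    profiles_ogm = stage("classify_ogm")(
        lambda: profiles_by_sample(ogm_segments, genome, cfg.classification, "ogm")
    )
    array_path = indir / "cnv_array.seg"
    profiles_array: Optional[dict[str, CnvProfile]] = None
    if array_path.exists():
        array_segments = gio.read_seg_file(array_path)
        profiles_array = stage("classify_array")(
            lambda: profiles_by_sample(array_segments, genome, cfg.classification, "array")
        )
    classified = pd.concat(
        [p.segments.assign(platform=p.platform)
         for p in list(profiles_ogm.values()) + list((profiles_array or {}).values())],
        ignore_index=True,
    )
    classified.to_csv(outdir / "classified_segments.tsv", sep="\t", index=False)
    _aneuploidy_table(profiles_ogm).to_csv(outdir / "aneuploidies_ogm.tsv", sep="\t", index=False)
    oncoprint_matrix(profiles_ogm, genome).to_csv(outdir / "oncoprint_matrix.tsv", sep="\t")
    results["profiles_ogm"] = profiles_ogm
    results["profiles_array"] = profiles_array
    meta["stages"]["classify_ogm"]["n_samples"] = len(profiles_ogm)

    # --- Concordance ------------------------------------------------------
    if profiles_array is not None:
        def _concord():
            tracks_a = {s: status_track(p) for s, p in profiles_ogm.items()}
            tracks_b = {s: status_track(p) for s, p in profiles_array.items()}
            shared = sorted(set(tracks_a) | set(tracks_b))
            per = []
            for sid in shared:
                ta = tracks_a.get(sid) or status_track(_empty_profile(sid, "ogm"))
                tb = tracks_b.get(sid) or status_track(_empty_profile(sid, "array"))
                per.append(sample_concordance(ta, tb, cfg.concordance_min_reciprocal))
            all_tracks = list(tracks_a.values()) + list(tracks_b.values())
            return cohort_concordance(per, all_tracks)

        concord = stage("concordance")(_concord)
        concord.per_sample.to_csv(outdir / "concordance_per_sample.tsv", sep="\t", index=False)
        concord.matrix.to_csv(outdir / "concordance_matrix.tsv", sep="\t")
        (outdir / "concordance_leaf_order.txt").write_text("\n".join(concord.leaf_order) + "\n")
        results["concordance"] = concord
        meta["stages"]["concordance"]["overall"] = round(concord.overall, 4)
    else:
        log.info("single platform supplied: concordance stage skipped")
        meta["stages"]["concordance"] = {"skipped": "single platform"}
        results["concordance"] = None

    # --- SV cascade -------------------------------------------------------
    sv_tumor = gio.read_sv_calls(indir / "sv_tumor.tsv")
    blood_path = indir / "sv_blood.tsv"
    sv_blood = gio.read_sv_calls(blood_path) if blood_path.exists() else sv_tumor.iloc[0:0]

    def _cascade():
        rare, common = filter_common(sv_tumor, cfg.cascade.af_threshold)
        nonpoly, poly = filter_polymorphic(rare, catalog, cfg.cascade)
        assert len(sv_tumor) == len(rare) + len(common)
        assert len(rare) == len(nonpoly) + len(poly)
        blood_patients = set(sv_blood["sample_id"].str.rstrip("b")) if len(sv_blood) else set()
        final_parts = []
        for sid, sub in nonpoly.groupby("sample_id", sort=True):
            patient = sid.rstrip("t")
            if patient in blood_patients:
                blood = sv_blood[sv_blood["sample_id"] == patient + "b"]
                somatic, germline = subtract_germline(sub, blood, cfg.cascade)
                final_parts.extend([somatic, germline])
            else:
                final_parts.append(infer_somatic_unmatched(sub))
        final = pd.concat(final_parts, ignore_index=True) if final_parts else nonpoly
        assert len(final) == len(nonpoly)
        return final, common, poly

    final_svs, common_svs, poly_svs = stage("sv_cascade")(_cascade)
    somatic_mask = final_svs["filter_state"].isin(["somatic", "presumed_somatic"])
    annotated = stage("annotate")(lambda: annotate_genes(final_svs, genes, cfg.cascade))
    gio.write_sv_calls(annotated, outdir / "svs_filtered.tsv")
    somatic = annotated[somatic_mask.values]
    recurrent = stage("recurrence")(lambda: find_recurrent(somatic, cfg.cascade))
    pd.DataFrame(
        [dict(chrom=r.interval.chrom, start=r.interval.start, end=r.interval.end,
              n_samples=r.n_samples, samples=",".join(sorted(r.samples)),
              sv_ids=",".join(r.sv_ids), dominant_gene=r.dominant_gene)
         for r in recurrent]
    ).to_csv(outdir / "recurrent_regions.tsv", sep="\t", index=False)
    tally(annotated, groups).to_csv(outdir / "sv_tally.tsv", sep="\t", index=False)
    gio.write_bed(
        [(r.chrom1, min(int(r.pos1), int(r.pos2)) if r.chrom1 == r.chrom2 else int(r.pos1),
          (max(int(r.pos1), int(r.pos2)) if r.chrom1 == r.chrom2 else int(r.pos1) + 1) or 1,
          r.sv_id)
         for r in somatic.itertuples(index=False)],
        outdir / "somatic_svs.bed",
    )
    results["svs"] = annotated
    results["somatic"] = somatic
    results["recurrent"] = recurrent
    meta["stages"]["sv_cascade"].update(
        n_input=len(sv_tumor), n_common=len(common_svs), n_polymorphic=len(poly_svs),
        n_somatic=int(somatic_mask.sum()),
    )

    # --- Fusion cross-validation ------------------------------------------
    fusions_path = indir / "fusions.tsv"
    if fusions_path.exists():
        fusions = gio.read_fusion_calls(fusions_path)
        def _xval():
            typed = classify_fusion_table(fusions, genes)
            pairs = sv_gene_pairs(somatic, genes, cfg.fusion_flank_bp)
            return cross_validate(pairs, typed, cfg.fusion_min_confidence)
        xval = stage("fusion_xval")(_xval)
        xval_table(xval).to_csv(outdir / "fusion_xval.tsv", sep="\t", index=False)
        results["xval"] = xval
        meta["stages"]["fusion_xval"]["n_both"] = sum(1 for r in xval if r.status == "both")
    else:
        results["xval"] = None

    # --- Group statistics ---------------------------------------------------
    prevalence = {sid: p.prevalence for sid, p in profiles_ogm.items()}
    sizes = pd.Series(groups).loc[list(prevalence)].value_counts()
    if len(sizes) >= 2 and (sizes >= 2).all():
        gs = stage("group_stats")(lambda: group_stats(prevalence, groups, cfg.alpha))
        gs.group_summary.to_csv(outdir / "group_prevalence.tsv", sep="\t", index=False)
        gs.tukey.to_csv(outdir / "tukey.tsv", sep="\t", index=False)
        results["group_stats"] = gs
        meta["stages"]["group_stats"].update(anova_f=round(gs.anova_f, 4),
                                             anova_p=float(gs.anova_p))
    else:
        log.info("group statistics skipped: need >= 2 groups with >= 2 samples")
        meta["stages"]["group_stats"] = {"skipped": "degenerate group sizes"}
        results["group_stats"] = None

    # --- Expression corroboration -----------------------------------------
    expr_path = indir / "expression.tsv"
    if expr_path.exists():
        expression = pd.read_csv(expr_path, sep="\t", index_col=0)
        calls = []
        gene_list = genes
        for sid, prof in sorted(profiles_ogm.items()):
            amps = prof.segments[prof.segments["state"] == "amplification"]
            for row in amps.itertuples(index=False):
                from .genome import GenomicInterval
                iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
                for g in gene_list:
                    if g.cancer_census and iv.overlaps(g.interval):
                        calls.append((g.symbol, sid))
        corro = expression_corroboration(expression, sorted(set(calls)))
        corro.to_csv(outdir / "expression_corroboration.tsv", sep="\t", index=False)
        results["corroboration"] = corro

    meta["total_seconds"] = round(time.time() - t0, 3)
    with open(outdir / "run_metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    results["metadata"] = meta
    return results


def _empty_profile(sample_id: str, platform: str) -> CnvProfile:
    empty = pd.DataFrame(columns=["sample_id", "chrom", "start", "end", "fract_cn",
                                  "confidence", "state", "size_class"])
    return CnvProfile(sample_id, platform, empty, [], set(), set(), 0)
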