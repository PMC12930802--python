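"""Run the somatic-SV filtering cascade and recurrence detection.

Removes common SVs (control-database AF > 1%), excludes known polymorphic
regions, subtracts germline events using matched blood where available
(translocation-class events are presumed somatic otherwise), annotates
genes/census/exonic status, clusters recurrent loci across samples, and
tallies SV types. The recurrence window is scaled to the 1/10-scale
synthetic genome (100 kbp).
"""

import argparse
from pathlib import Path

import pandas as pd

from ogmsv import io as gio
from ogmsv.svfilter import (
    CascadeConfig,
    annotate_genes,
    filter_common,
    filter_polymorphic,
    find_recurrent,
    infer_somatic_unmatched,
    subtract_germline,
    tally,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--recurrence-window", type=int, default=100_000)
    args = ap.parse_args()
    cohort, out = Path(args.cohort), Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cascade = CascadeConfig(recurrence_window_bp=args.recurrence_window)

    genes = gio.read_gene_model(cohort / "genes.bed")
    catalog = gio.read_catalog(cohort / "catalog.bed")
    tumor = gio.read_sv_calls(cohort / "sv_tumor.tsv")
    blood = gio.read_sv_calls(cohort / "sv_blood.tsv")
    samples = pd.read_csv(cohort / "samples.tsv", sep="\t")
    groups = dict(zip(samples.sample_id, samples.group))

    rare, common = filter_common(tumor, cascade.af_threshold)
    nonpoly, poly = filter_polymorphic(rare, catalog, cascade)
    blood_samples = set(blood.sample_id)
    parts = []
    for sid, sub in nonpoly.groupby("sample_id", sort=True):
        bid = sid[:-1] + "b"
        if bid in blood_samples:
            somatic, germline = subtract_germline(sub, blood[blood.sample_id == bid], cascade)
            parts.extend([somatic, germline])
        else:
            parts.append(infer_somatic_unmatched(sub))
    final = pd.concat(parts, ignore_index=True)
    annotated = annotate_genes(final, genes, cascade)
    gio.write_sv_calls(annotated, out / "svs_filtered.tsv")

    somatic = annotated[annotated.filter_state.isin(["somatic", "presumed_somatic"])]
    regions = find_recurrent(somatic, cascade)
    pd.DataFrame(
        [dict(chrom=r.interval.chrom, start=r.interval.start, end=r.interval.end,
              n_samples=r.n_samples, dominant_gene=r.dominant_gene,
              sv_ids=",".join(r.sv_ids)) for r in regions]
    ).to_csv(out / "recurrent_regions.tsv", sep="\t", index=False)
    tally(annotated, groups).to_csv(out / "sv_tally.tsv", sep="\t", index=False)

    print(f"input SVs: {len(tumor)}; common removed: {len(common)}; "
          f"polymorphic removed: {len(poly)}")
    states = final.filter_state.value_counts().to_dict()
    print(f"final states: {states}")
    multi = [r for r in regions if r.n_samples >= 2 and r.dominant_gene]
    print(f"recurrent regions (>= 2 samples): {len(regions)}; "
          f"top gene hits: {[r.dominant_gene for r in multi[:5]]}")


if __name__ == "__main__":
    main()
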