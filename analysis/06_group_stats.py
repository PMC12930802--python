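"""Compare CNV prevalence across molecular groups.

One-way ANOVA on the number of chromosomes affected by CNVs per tumor,
followed by Tukey's HSD for pairwise group comparisons, plus expression
corroboration of amplified cancer-census genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from ogmsv import io as gio
from ogmsv.cnv import profiles_by_sample
from ogmsv.genome import GenomicInterval
from ogmsv.stats import expression_corroboration, group_stats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    cohort, out = Path(args.cohort), Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    genome = gio.load_genome(cohort / "cytoband.txt")
    genes = gio.read_gene_model(cohort / "genes.bed")
    samples = pd.read_csv(cohort / "samples.tsv", sep="\t")
    profiles = profiles_by_sample(gio.read_cnv_segments(cohort / "cnv_ogm.tsv"), genome)

    prevalence = {s: p.prevalence for s, p in profiles.items()}
    groups = dict(zip(samples.sample_id, samples.group))
    res = group_stats(prevalence, groups)
    res.group_summary.to_csv(out / "group_prevalence.tsv", sep="\t", index=False)
    res.tukey.to_csv(out / "tukey.tsv", sep="\t", index=False)

    print("CNV prevalence by group (mean +/- SD):")
    for _, row in res.group_summary.iterrows():
        print(f"  {row['group']:<12} {row['mean']:5.2f} +/- {row['sd']:.2f} (n={row['n']})")
    print(f"one-way ANOVA: F = {res.anova_f:.2f}, p = {res.anova_p:.3g}")
    sig = res.tukey[res.tukey.p_adj < res.alpha]
    print(f"Tukey HSD pairs with adjusted p < {res.alpha}: {len(sig)}/{len(res.tukey)}")

    expr = pd.read_csv(cohort / "expression.tsv", sep="\t", index_col=0)
    calls = []
    for sid, prof in sorted(profiles.items()):
        amps = prof.segments[prof.segments.state == "amplification"]
        for row in amps.itertuples(index=False):
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
            calls.extend((g.symbol, sid) for g in genes
                         if g.cancer_census and iv.overlaps(g.interval))
    corro = expression_corroboration(expr, sorted(set(calls)))
    corro.to_csv(out / "expression_corroboration.tsv", sep="\t", index=False)
    if len(corro):
        hits = corro[corro.status == "corroborated"]
        print(f"amplified census genes corroborated by expression: "
              f"{[(r.gene, r.sample_id) for r in hits.itertuples(index=False)]}")
    else:
        print("no amplified cancer-census genes in this cohort")


if __name__ == "__main__":
    main()
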