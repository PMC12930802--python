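"""Cross-validate DNA-level somatic SVs against RNA-level fusion calls.

Derives candidate gene pairs from somatic SVs whose breakpoints fall in
two distinct genes, infers each RNA fusion's DNA event type from
breakpoint geometry and gene strands, and partitions gene pairs into
both / dna_only / rna_only with a type-consistency flag.
"""

import argparse
from pathlib import Path

import pandas as pd

from ogmsv import io as gio
from ogmsv.fusion import classify_fusion_table, cross_validate, sv_gene_pairs, xval_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    cohort, out = Path(args.cohort), Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    genes = gio.read_gene_model(cohort / "genes.bed")
    fusions = classify_fusion_table(gio.read_fusion_calls(cohort / "fusions.tsv"), genes)
    svs = gio.read_sv_calls(out / "svs_filtered.tsv")
    somatic = svs[svs.filter_state.isin(["somatic", "presumed_somatic"])]

    pairs = sv_gene_pairs(somatic, genes)
    records = cross_validate(pairs, fusions)
    xval_table(records).to_csv(out / "fusion_xval.tsv", sep="\t", index=False)

    by_status = pd.Series([r.status for r in records]).value_counts().to_dict()
    both = [r for r in records if r.status == "both"]
    by_type = fusions.event_type.value_counts().to_dict()
    print(f"DNA candidate gene pairs: {len(pairs)}; RNA fusions: {len(fusions)}")
    print(f"match status counts: {by_status}")
    print(f"type-consistent among 'both': {sum(r.type_consistent for r in both)}/{len(both)}")
    print(f"RNA fusion event types: {by_type}")


if __name__ == "__main__":
    main()
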