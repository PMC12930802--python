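"""Classify fractional-CN segments and call aneuploidies per sample.

Applies the CN-state thresholds (balanced 1.800-2.200, gain to 3.500,
amplification above, hemizygous below 1.800, homozygous below 0.800),
focal/partial sizing at 3 Mbp, and the 0.630/0.315 fractional-CN-size
rules for whole-chromosome and arm aneuploidies.
"""

import argparse
from pathlib import Path

import pandas as pd

from ogmsv import io as gio
from ogmsv.cnv import oncoprint_matrix, profiles_by_sample


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    cohort, out = Path(args.cohort), Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    genome = gio.load_genome(cohort / "cytoband.txt")
    segments = gio.read_cnv_segments(cohort / "cnv_ogm.tsv")
    profiles = profiles_by_sample(segments, genome, platform="ogm")

    classified = pd.concat([p.segments for p in profiles.values()], ignore_index=True)
    classified.to_csv(out / "classified_segments.tsv", sep="\t", index=False)
    rows = [dict(sample_id=s, chrom=c.chrom, scope=c.scope, direction=c.direction,
                 fraction=round(c.fraction, 4))
            for s, p in sorted(profiles.items()) for c in p.aneuploidies]
    pd.DataFrame(rows).to_csv(out / "aneuploidies.tsv", sep="\t", index=False)
    oncoprint_matrix(profiles, genome).to_csv(out / "oncoprint_matrix.tsv", sep="\t")

    prevalence = pd.Series({s: p.prevalence for s, p in profiles.items()})
    n_iso = sum(bool(p.isochromosome_chroms) for p in profiles.values())
    n_complex = sum(bool(p.complex_chroms) for p in profiles.values())
    print(f"classified {len(classified)} segments in {len(profiles)} samples")
    print(f"CNV prevalence (chromosomes affected per tumor): "
          f"mean {prevalence.mean():.2f}, range {prevalence.min()}-{prevalence.max()}")
    print(f"samples with isochromosome pattern: {n_iso}; with complex chromosomes: {n_complex}")


if __name__ == "__main__":
    main()
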