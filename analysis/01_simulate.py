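"""Generate the ground-truthed synthetic cohort.

Renders 29 tumors across the five molecular groups (WNT 3, SHH-infant 6,
SHH-child 5, Group 3 4, Group 4 11) with matched blood for 18 patients,
two CNV platforms, SV and fusion tables, and the machine-readable truth.
"""

import argparse
from pathlib import Path

from ogmsv.simulate import DEFAULT_CONFIG, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/cohort")
    args = ap.parse_args()

    truth = generate_cohort(DEFAULT_CONFIG, seed=args.seed, outdir=args.outdir)
    print(f"cohort written to {args.outdir}")
    print(truth.samples.groupby("group").size().rename("n_samples").to_string())
    print(f"planted CN regions: {len(truth.truth_cn)}")
    print(f"planted SVs: {len(truth.truth_sv)} "
          f"({(truth.truth_sv.origin == 'germline').sum()} germline / "
          f"{(truth.truth_sv.origin == 'somatic').sum()} somatic)")
    print(f"planted RNA fusion records: {len(truth.fusions)}")


if __name__ == "__main__":
    main()
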