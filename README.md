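# ogmsv

Downstream analysis of optical-genome-mapping (OGM) copy-number and
structural-variant call-sets in pediatric brain-tumor cohorts, built for
the medulloblastoma setting: five molecular groups (WNT, SHH-infant,
SHH-child, Group 3, Group 4), each with characteristic copy-number
archetypes such as monosomy 6, isochromosome 17q and focal oncogene
amplifications.

OGM images fluorescently labelled ultra-long DNA molecules in
nanochannels and reports structural variants from ~500 bp upward; this
package consumes the *call-sets* such a workflow produces (fractional-CN
segment tables, SMAP-style SV tables) together with array-style SEG
files, polymorphic-region catalogs, gene models and RNA fusion tables,
and implements the downstream computation:

- **CNV classification** — a segment with fractional copy number CN is
  *balanced* when 1.800 ≤ CN ≤ 2.200, a *gain* when 2.200 < CN ≤ 3.500,
  an *amplification* when CN > 3.500, a *hemizygous deletion* when
  CN < 1.800 and a *homozygous deletion* when CN < 0.800; segments are
  *focal* (< 3 Mbp) or *partial* (> 3 Mbp). Whole-chromosome aneuploidy
  is called when the altered fraction of the chromosome (the fractional
  CN size) is ≥ 0.630, an arm event at ≥ 0.315; chromosomes mixing gains
  and losses are flagged *complex*, and opposite-direction arm calls flag
  an isochromosome pattern.
- **Cross-platform concordance** — each sample's gain/loss base sets from
  two platforms are compared with the Sorensen (Dice) coefficient
  S = 2|A∩B| / (|A| + |B|), plus event-level matching by reciprocal
  overlap, a pairwise similarity matrix with average-linkage clustering,
  and a cohort-level concordance that excludes samples balanced on both
  platforms.
- **Somatic SV filtering** — rare-SV selection (control-database allele
  frequency ≤ 1%), polymorphic-region exclusion, germline subtraction
  against matched blood, the presumed-somatic rule for translocation-class
  events without a matched normal, gene / cancer-census / exonic
  annotation, cross-sample recurrence clustering and type tallies.
- **Fusion cross-validation** — gene pairs nominated by DNA-level SV
  breakpoints are matched against RNA-level fusion calls, with the DNA
  event type (deletion / duplication / inversion / translocation) inferred
  from breakpoint geometry and gene strands.
- **Synthetic cohorts** — a ground-truthed generator renders the same
  truth through an OGM-like and an array-like platform (purity mixture
  2 + p·(CN−2), platform-specific boundary jitter and detection floor),
  with germline/somatic SV sets and planted RNA fusion evidence, so every
  stage is testable against known truth.

## Worked example

Run the analysis scripts in order (each is a thin driver over the
library; all outputs land in `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_classify_cnv.py
python analysis/03_concordance.py
python analysis/04_filter_svs.py
python analysis/05_fusion_xval.py
python analysis/06_group_stats.py
```

With seed 1 this prints, among other lines:

```
planted SVs: 1740 (1044 germline / 696 somatic)
CNV prevalence (chromosomes affected per tumor): mean 6.62, range 1-18
samples with isochromosome pattern: 12; with complex chromosomes: 14
per-sample combined Sorensen >= 0.9 in 29/29 samples
overall event-level concordance: 100.0%
input SVs: 1740; common removed: 328; polymorphic removed: 67
final states: {'undetermined': 446, 'somatic': 432, 'germline': 402, 'presumed_somatic': 65}
one-way ANOVA: F = 19.30, p = 3.21e-07
amplified census genes corroborated by expression: [('GPC5L', 'S15t')]
```

Reading this: the generator planted 29 tumors whose CNV burden differs
strongly by group (Group 3 highest), the two platform renderings of the
same truth agree almost perfectly at default noise, the filtering cascade
reduces 1,740 raw SV calls to 432 confirmed somatic events (plus 65
presumed-somatic translocation-class events in samples without a matched
blood), and the one focally amplified cancer gene is also the cohort's
expression outlier. Equivalent orchestration is available as a single
command: `ogmsv run-all --indir results/cohort --outdir results`.

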