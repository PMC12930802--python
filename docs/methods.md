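# Methods

## Coordinates and interval algebra

All coordinates are 0-based half-open, so an interval's length is
`end − start`; the printed region chr13:90,684,670–92,265,557 measures
exactly 1,580,887 bp under this convention, which is what fixed it. File
readers normalize chromosome names to the `chr` prefix and ingest
coordinates unchanged. Interval sets are kept normalized (per-chromosome
sorted, overlapping or touching intervals merged); public set operations
normalize defensively and warn. Intersection uses a two-pointer sweep and
is tested for exact equality against per-base boolean-vector brute force
on randomized toy genomes.

SV records carry `size_bp` as an independent field rather than deriving
it from the breakpoint span: for small insertions the two quantities are
genuinely different (an inserted sequence has a size but almost no span),
and call-sets in the wild report sizes that disagree with the span even
for deletions. Nothing in the cascade infers a small-SV size from its
breakpoints.

## CNV classification

Fractional copy number (fractCN) is the raw, purity-attenuated CN
estimate of a bulk tumor segment. Classification applies fixed
thresholds in this evaluation order: CN < 0.800 homozygous deletion,
CN < 1.800 hemizygous deletion, CN ≤ 2.200 balanced, CN ≤ 3.500 gain,
else amplification. Balanced segments are excluded from the CNV
call-set. Size classes split at 3 Mbp; exactly 3 Mbp is classed focal
for determinism, since the defining inequalities (`< 3 Mbp` focal,
`> 3 Mbp` partial) leave the boundary unassigned.

**Aneuploidy.** Per chromosome and direction (gain-type = gain ∪
amplification, loss-type = hemizygous ∪ homozygous deletion) the
fractional CN size is the summed length of that direction's segments
divided by the *chromosome* length. At ≥ 0.630 a whole-chromosome call
is emitted (suppressing arm calls in that direction); otherwise at
≥ 0.315, and when ≥ 90% of the altered bases lie on a single arm, that
arm's call is emitted. The chromosome-length denominator was chosen
because 0.315 is exactly half of 0.630, which is what one expects when
both thresholds are expressed on the same scale; a config switch
(`arm_frac_denominator="arm"`) provides the arm-length alternative. The
90% concentration requirement is what distinguishes a genuine arm event
from alterations scattered across both arms.

**Complex and isochromosome signatures.** A chromosome is complex when
it carries both gain-type and loss-type segments (the alternating
fractCN pattern 2.223 / 1.646 / 2.834 is the canonical example) or at
least three state alternations among its non-balanced segments. An
isochromosome pattern is one arm's gain call concomitant with the other
arm's loss call — the i17q layout.

Sex chromosomes run through the same diploid thresholds by default; no
purity or ploidy correction is applied to observed fractCN (the pipeline
classifies raw values), and subclonality is out of scope.

## Concordance

Each classified profile reduces to a gain track and a loss track
(normalized base sets over the non-balanced segments). Per direction the
Sorensen coefficient is S = 2|A∩B|/(|A|+|B|), undefined when both sets
are empty. The per-sample *combined* coefficient is the span-weighted
mean of the defined per-direction coefficients (weights |A|+|B|), which
reduces to the single defined value when only one direction has events.
Samples with no events on either platform are excluded from cohort
summaries rather than scored 1 — an empty-vs-empty comparison carries no
information about agreement.

Event-level concordance merges each direction's track into maximal
events and matches them greedily, best reciprocal overlap first, with a
0.5 reciprocal-overlap floor; the cohort concordance is
(matched events)/(union events) over non-excluded samples. Both the
overlap floor and the event/base-level mode are configuration, recorded
in run metadata, because "detected by both platforms" admits several
operational definitions; event-level at 0.5 is the default. The
similarity matrix over all profiles is clustered with average linkage on
1 − S, with deterministic lexicographic tie-breaking via pre-sorted
labels.

## The somatic-SV cascade

Stages apply in order, each conserving counts (retained + removed =
input) and only moving the `filter_state` forward:

1. **Common-SV removal.** Rare means control-database allele frequency
   ≤ 1%; an absent AF means the variant was never seen in controls and
   is kept.
2. **Polymorphic-region exclusion.** Deletions/duplications are removed
   on reciprocal overlap ≥ 0.5 with a catalog region of AF > 1%;
   insertions/inversions when both breakpoints fall inside one such
   region; translocation-class events never — population catalogs do not
   describe them reliably.
3. **Germline subtraction** (matched blood available): a tumor SV is
   germline iff a blood SV of the same type matches — reciprocal overlap
   ≥ 0.5 or both breakpoints within 10 kbp for deletions, duplications
   and inversions; breakpoint within 10 kbp and size within 30% for
   insertions; both partner breakpoints within 50 kbp (either
   orientation) for translocations and intrachromosomal fusions.
4. **Presumed-somatic inference** (no matched blood): translocation-class
   events are flagged presumed-somatic — in matched patients these
   classes are essentially never germline — while other types remain
   undetermined rather than being guessed.

The overlap and distance tolerances in stages 2–4 (0.5 reciprocal,
10 kbp, 30%, 50 kbp, ±1 kbp annotation flanks, 1 Mbp recurrence window)
are package defaults chosen at the scale of OGM breakpoint uncertainty,
exposed in `CascadeConfig` and echoed into run metadata; they are not
derived quantities. Gene annotation intersects CNV-type SVs over their
full footprint and breakpoint-class SVs over ±1 kbp flanks, flagging
cancer-census membership and exonic versus intronic-only overlap.
Recurrence clusters breakpoint-1 positions per chromosome by single
linkage at the window distance and reports clusters spanning ≥ 2 distinct
samples with their dominant gene. SVs with a breakpoint in a gap-like
cytoband stain would be flagged rather than removed; the synthetic
genome contains no such regions.

## Fusion cross-validation

A somatic SV whose breakpoints (±10 kbp flank; a containing gene always
beats a flank-only neighbor) fall in two distinct genes nominates an
unordered gene pair; one genic plus one intergenic breakpoint yields a
one-gene record that can never match an RNA call. RNA fusions are typed
from geometry: different chromosomes → translocation; same chromosome
with discordant strands → inversion; concordant strands → deletion when
the 5′ gene lies transcriptionally upstream (genomically before for
plus-strand pairs, after for minus-strand pairs — the rule mirrors under
strand flip), else duplication. Matching ignores 5′/3′ order because DNA
breakpoints are unoriented at the gene level; confidence gating defaults
to high-only. Reading frame is pass-through metadata: computing it needs
transcript sequence, which is out of scope.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are not tuned
per experiment.

**Genome.** The default cohort genome has the 24 human chromosomes at
1/10 of their real lengths with centromeres placed at 46–48% of each
chromosome. Mid-chromosome centromeres are deliberate: they put
single-arm events inside the arm-call window [0.315, 0.630) under the
chromosome-length denominator, so planted isochromosomes are expressible.
A 6-chromosome toy genome (10–60 Mbp) exists for fast exhaustive work,
and the oracle tests use 100 kbp two-chromosome genomes where per-base
brute force is exact and instant. ~200 non-overlapping genes are
scattered, ~5% census-flagged, including two fixed landmarks: `NRX1L`, a
1.1 Mbp gene with a 249 kbp second intron that receives planted
recurrent intronic deletions, and `GPC5L` inside the fixed chr13
focal-amplification locus.

**Copy-number archetypes** (per group: fixed events, rates, altered-
chromosome target mean ± SD): WNT — monosomy 6 always, occasional chrX/
chr11/chrY loss, target 2.67 ± 0.58; SHH-infant — joint trisomy 2+3 with
probability 1/3, target 2.00 ± 1.10; SHH-child — target 6.80 ± 3.49,
complex chromosome probability 0.3; Group 3 — i17q probability 0.75,
focal amplification probability 0.25 (CN 10–20), complex 0.75, recurrence
0.75, target 14.25 ± 3.30; Group 4 — i17q probability 9/11 with trisomy
17 otherwise, complex 0.5, recurrence 0.2, target 8.00 ± 4.90. Group
sizes default to 3/6/5/4/11 tumors with matched blood for the first 18
patients. Fill-in events are drawn per chromosome (whole, arm or focal);
the first fill-in is always a whole-chromosome event so that every
CNV-bearing sample carries at least one multi-megabase event — small
focal events alone would make the per-sample Sorensen between platform
renderings jitter-dominated, which is not how these genomes look.

**Rendering.** Observed fractCN follows the linear purity mixture
2 + p·(CN_true − 2) with purity uniform in [0.8, 1.0] (high-tumor-content
specimens) plus Gaussian noise (sd 0.05, truncated at 0). The OGM-like
platform jitters boundaries with sd 2 kbp and keeps segments ≥ 500 bp;
the array-like platform jitters with sd 50 kbp, keeps segments ≥ 50 kbp,
and drops segments with |log2(CN/2)| < 0.1 — its detection floor, which
makes low-purity single-copy gains vanish on the array but not on OGM
(at purity 0.10 a trisomy renders at fractCN 2.1, log2 ratio ≈ 0.07).

**SVs.** 60 planted SVs per tumor, 60% germline / 40% somatic. Germline
SVs (deletion .4 / insertion .3 / duplication .2 / inversion .1) appear
identically in the matched blood rendering (optionally with uniform
±jitter); 30% receive a control AF above the 1% bar, and 20% of the rare
CNV-type germline SVs are placed inside hot catalog regions so the
polymorphic stage does real work. Half of somatic SVs are genic gene-pair
events whose DNA type is derived from the chosen genes' geometry, making
planted DNA type and RNA event type consistent by construction; 40% of
eligible genic somatic SVs receive a high-confidence RNA fusion record
(exactly round(fraction·n), deterministically sampled). The generator
rejects somatic placements that would coincidentally satisfy the
germline-match or polymorphic-removal predicates, and rare germline
placements that would hit a hot region: planted labels are then exactly
recoverable at zero noise, so any recovery failure indicates a pipeline
defect rather than generator ambiguity.

**What the generator does not emulate:** segmentation artifacts,
wave/GC noise, subclonal mixtures, breakpoint microhomology, reference
gaps and mappability, or realistic per-platform SV sensitivity curves.
Passing recovery tests therefore demonstrates correctness of the
*rules*, not detection performance on real specimens.

## Statistics

Group comparison of CNV prevalence uses one-way ANOVA with Tukey's HSD
for pairwise means (statsmodels); α = 0.05 is reported, never used to
drop rows, and no additional FDR layer is applied beyond Tukey. The
degenerate all-identical case returns F = 0, p = 1 explicitly (the
ratio 0/0 is otherwise undefined). Expression corroboration flags an
amplified gene in a sample when that sample is the cohort maximum and
exceeds the cohort median by more than 2 × MAD; non-maximal samples
above the bar are reported as elevated-not-maximal.

## Problem sizes and numerical notes

Test and acceptance runs use the default 29-sample cohort on the
1/10-scale genome (~1,700 SVs, ~220 CN segments), where the full
pipeline completes in seconds; randomized oracle comparisons run 200–300
instances per operation on 100 kbp genomes. On the scaled genome the
recurrence window is scaled correspondingly (100 kbp); the 1 Mbp default
applies to full-scale data. All randomness flows from a single numpy
Generator per entry point, so fixed seeds reproduce byte-identical file
sets; report files avoid floating-point instability by rounding rendered
values (fractCN to 4 decimals, seg.mean to 6).

## Known limitations

- The arm-threshold denominator and the event-matching definition are
  disambiguation choices among readings the thresholds themselves do not
  fix; both are configurable and recorded in run metadata.
- Cohort-level headline numbers from real tumor cohorts (overall
  concordance percentages, per-tumor SV counts) are properties of
  patient data this package does not ship; the pipeline reproduces the
  procedures and verifies them on synthetic truth instead.
- Unmatched samples leave non-translocation SVs undetermined by design;
  no imputation of somatic status is attempted.
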