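"""The SV filtering cascade against constructed cases and quadratic oracles."""

import numpy as np
import pandas as pd
import pytest

from _oracles import germline_ids_oracle, polymorphic_removed_oracle, recurrence_oracle
from ogmsv.genome import CatalogRegion, GeneRecord, GenomicInterval
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

SV_COLS = ["sv_id", "sample_id", "type", "chrom1", "pos1", "chrom2", "pos2",
           "size_bp", "confidence", "control_af"]


def sv_row(sv_id, svtype, chrom1, pos1, chrom2=None, pos2=None, size=None,
           af=np.nan, sample="s1"):
    if chrom2 is None:
        chrom2 = chrom1
    if pos2 is None:
        pos2 = pos1 + (size or 100)
    if size is None:
        size = abs(pos2 - pos1)
    return dict(sv_id=sv_id, sample_id=sample, type=svtype, chrom1=chrom1,
                pos1=pos1, chrom2=chrom2, pos2=pos2, size_bp=size,
                confidence=0.9, control_af=af)


def sv_frame(rows):
    return pd.DataFrame(rows, columns=SV_COLS)


class TestFilterCommon:
    def test_threshold_boundaries(self):
        svs = sv_frame([
            sv_row("a", "deletion", "chr1", 100, size=500, af=0.05),
            sv_row("b", "deletion", "chr1", 5_000, size=500, af=0.01),
            sv_row("c", "deletion", "chr1", 9_000, size=500, af=np.nan),
        ])
        rare, common = filter_common(svs)
        assert list(rare.sv_id) == ["b", "c"]
        assert list(common.sv_id) == ["a"]
        assert (rare.filter_state == "rare").all()

    def test_empty_input(self):
        rare, common = filter_common(sv_frame([]))
        assert rare.empty and common.empty

    def test_bad_af_rejected(self):
        svs = sv_frame([sv_row("a", "deletion", "chr1", 100, size=500, af=1.5)])
        with pytest.raises(ValueError):
            filter_common(svs)

    def test_generator_truth_counts(self, zero_noise_cohort):
        t = zero_noise_cohort
        rare, common = filter_common(t.sv_tumor)
        planted_common = (t.truth_sv.af_class == "common").sum()
        assert len(common) == planted_common
        assert len(rare) == len(t.sv_tumor) - planted_common


class TestFilterPolymorphic:
    CATALOG = [
        CatalogRegion(GenomicInterval("chr1", 10_000, 20_000), 0.05),
        CatalogRegion(GenomicInterval("chr1", 50_000, 60_000), 0.001),  # below AF bar
    ]

    def test_deletion_in_hot_region_removed(self):
        svs = sv_frame([sv_row("a", "deletion", "chr1", 10_500, pos2=19_500)])
        kept, removed = filter_polymorphic(svs, self.CATALOG)
        assert list(removed.sv_id) == ["a"]

    def test_low_reciprocal_overlap_retained(self):
        svs = sv_frame([sv_row("a", "deletion", "chr1", 18_000, pos2=48_000)])
        kept, removed = filter_polymorphic(svs, self.CATALOG)
        assert list(kept.sv_id) == ["a"]

    def test_cold_region_never_removes(self):
        svs = sv_frame([sv_row("a", "duplication", "chr1", 50_500, pos2=59_500)])
        kept, _ = filter_polymorphic(svs, self.CATALOG)
        assert list(kept.sv_id) == ["a"]

    def test_translocation_never_removed(self):
        svs = sv_frame([sv_row("a", "translocation", "chr1", 15_000, "chr2", 15_000, size=0)])
        kept, _ = filter_polymorphic(svs, self.CATALOG)
        assert list(kept.sv_id) == ["a"]

    def test_insertion_requires_both_breakpoints_inside(self):
        svs = sv_frame([
            sv_row("in", "insertion", "chr1", 12_000, pos2=12_400, size=900),
            sv_row("out", "insertion", "chr1", 19_900, pos2=21_000, size=900),
        ])
        kept, removed = filter_polymorphic(svs, self.CATALOG)
        assert list(removed.sv_id) == ["in"] and list(kept.sv_id) == ["out"]

    def test_matches_quadratic_oracle_randomized(self, rng):
        for _ in range(200):
            catalog = []
            for _k in range(int(rng.integers(0, 6))):
                s = int(rng.integers(0, 90_000))
                catalog.append((("chr1"), s, s + int(rng.integers(500, 8_000)),
                                float(rng.choice([0.001, 0.05]))))
            cat_objs = [CatalogRegion(GenomicInterval(c, s, e), a) for c, s, e, a in catalog]
            rows = []
            for k in range(int(rng.integers(0, 10))):
                svtype = str(rng.choice(["deletion", "duplication", "insertion",
                                         "inversion", "translocation"]))
                p1 = int(rng.integers(0, 90_000))
                if svtype == "translocation":
                    rows.append(sv_row(f"v{k}", svtype, "chr1", p1, "chr2", p1, size=0))
                else:
                    rows.append(sv_row(f"v{k}", svtype, "chr1", p1,
                                       pos2=p1 + int(rng.integers(100, 9_000))))
            svs = sv_frame(rows)
            _, removed = filter_polymorphic(svs, cat_objs)
            want = polymorphic_removed_oracle([r for r in rows], catalog)
            assert set(removed.sv_id) == want


class TestSubtractGermline:
    def test_self_subtraction_is_all_germline(self):
        t = sv_frame([sv_row("a", "deletion", "chr1", 1_000, pos2=9_000),
                      sv_row("b", "insertion", "chr2", 5_000, pos2=5_100, size=800)])
        somatic, germline = subtract_germline(t, t)
        assert somatic.empty and len(germline) == 2

    def test_empty_blood_all_somatic(self):
        t = sv_frame([sv_row("a", "deletion", "chr1", 1_000, pos2=9_000)])
        somatic, germline = subtract_germline(t, t.iloc[0:0])
        assert len(somatic) == 1 and germline.empty

    def test_insertion_size_tolerance(self):
        t = sv_frame([sv_row("a", "insertion", "chr1", 1_000, pos2=1_100, size=1_000)])
        close = sv_frame([sv_row("x", "insertion", "chr1", 2_000, pos2=2_100, size=1_200,
                                 sample="s1")])
        far = sv_frame([sv_row("x", "insertion", "chr1", 2_000, pos2=2_100, size=2_000,
                               sample="s1")])
        assert subtract_germline(t, close)[1].sv_id.tolist() == ["a"]
        assert subtract_germline(t, far)[0].sv_id.tolist() == ["a"]

    def test_translocation_partner_tolerance(self):
        t = sv_frame([sv_row("a", "translocation", "chr1", 100_000, "chr2", 200_000, size=0)])
        b_near = sv_frame([sv_row("x", "translocation", "chr2", 230_000, "chr1", 130_000,
                                  size=0)])
        b_far = sv_frame([sv_row("x", "translocation", "chr1", 100_000, "chr2", 300_000,
                                 size=0)])
        assert subtract_germline(t, b_near)[1].sv_id.tolist() == ["a"]  # reversed partners
        assert subtract_germline(t, b_far)[0].sv_id.tolist() == ["a"]

    def test_matches_quadratic_oracle_randomized(self, rng):
        types = ["deletion", "duplication", "inversion", "insertion", "translocation"]
        for _ in range(200):
            def rand_rows(prefix, n):
                rows = []
                for k in range(n):
                    svtype = str(rng.choice(types))
                    p1 = int(rng.integers(0, 200_000))
                    if svtype == "translocation":
                        rows.append(sv_row(f"{prefix}{k}", svtype, "chr1", p1, "chr2",
                                           int(rng.integers(0, 200_000)), size=0))
                    elif svtype == "insertion":
                        rows.append(sv_row(f"{prefix}{k}", svtype, "chr1", p1,
                                           pos2=p1 + 50, size=int(rng.integers(100, 5_000))))
                    else:
                        rows.append(sv_row(f"{prefix}{k}", svtype, "chr1", p1,
                                           pos2=p1 + int(rng.integers(500, 40_000))))
                return rows
            t_rows = rand_rows("t", int(rng.integers(0, 8)))
            b_rows = rand_rows("b", int(rng.integers(0, 8)))
            somatic, germline = subtract_germline(sv_frame(t_rows), sv_frame(b_rows))
            want = germline_ids_oracle(t_rows, b_rows)
            assert set(germline.sv_id) == want
            assert set(somatic.sv_id) == {r["sv_id"] for r in t_rows} - want

    def test_generator_truth_recovery(self, zero_noise_cohort):
        t = zero_noise_cohort
        truth = t.truth_sv.set_index("sv_id")
        matched = set(t.samples[t.samples.matched_normal].sample_id)
        rare, _ = filter_common(t.sv_tumor)
        nonpoly, _ = filter_polymorphic(rare, t.catalog)
        total = good = 0
        for sid, sub in nonpoly.groupby("sample_id"):
            if sid not in matched:
                continue
            blood = t.sv_blood[t.sv_blood.sample_id == sid[:-1] + "b"]
            somatic, germline = subtract_germline(sub, blood)
            for df, label in ((somatic, "somatic"), (germline, "germline")):
                for svid in df.sv_id:
                    total += 1
                    good += truth.loc[svid, "origin"] == label
        assert total > 0 and good == total  # exact recovery at zero jitter


class TestUnmatchedInference:
    def test_translocation_class_presumed_somatic(self):
        svs = sv_frame([
            sv_row("a", "translocation", "chr1", 100, "chr2", 200, size=0),
            sv_row("b", "intrachr_fusion", "chr1", 100, pos2=2_000_000, size=0),
            sv_row("c", "deletion", "chr1", 100, pos2=9_000),
        ])
        out = infer_somatic_unmatched(svs)
        assert dict(zip(out.sv_id, out.filter_state)) == {
            "a": "presumed_somatic", "b": "presumed_somatic", "c": "undetermined"}

    def test_empty(self):
        assert infer_somatic_unmatched(sv_frame([])).empty


GENES = [
    GeneRecord("CENSUS1", GenomicInterval("chr1", 10_000, 30_000), "+",
               (GenomicInterval("chr1", 11_000, 12_000), GenomicInterval("chr1", 25_000, 26_000)),
               cancer_census=True),
    GeneRecord("PLAIN1", GenomicInterval("chr1", 50_000, 80_000), "-",
               (GenomicInterval("chr1", 51_000, 52_000), GenomicInterval("chr1", 78_000, 79_000)),
               cancer_census=False),
]


class TestAnnotateGenes:
    def test_census_exon_hit(self):
        svs = sv_frame([sv_row("a", "deletion", "chr1", 24_000, pos2=27_000)])
        out = annotate_genes(svs, GENES)
        assert out.loc[0, "genes"] == "CENSUS1"
        assert bool(out.loc[0, "cancer_census"]) and bool(out.loc[0, "exonic"])

    def test_intronic_only_deletion(self):
        # wholly inside one intron, touching no exon
        svs = sv_frame([sv_row("a", "deletion", "chr1", 54_000, pos2=70_000)])
        out = annotate_genes(svs, GENES)
        assert out.loc[0, "genes"] == "PLAIN1"
        assert not out.loc[0, "exonic"] and bool(out.loc[0, "intronic_only"])

    def test_no_gene_overlap(self):
        svs = sv_frame([sv_row("a", "deletion", "chr1", 90_000, pos2=95_000)])
        out = annotate_genes(svs, GENES)
        assert out.loc[0, "genes"] == "" and not out.loc[0, "cancer_census"]

    def test_breakpoint_type_uses_flanks(self):
        svs = sv_frame([sv_row("a", "translocation", "chr1", 29_500, "chr2", 500, size=0)])
        out = annotate_genes(svs, GENES)
        assert out.loc[0, "genes"] == "CENSUS1"


class TestRecurrence:
    def test_five_samples_one_region(self):
        rows = [sv_row(f"v{k}", "deletion", "chr2", 1_000_000 + 40_000 * k,
                       pos2=1_010_000 + 40_000 * k, sample=f"s{k}") for k in range(5)]
        regions = find_recurrent(pd.DataFrame(rows))
        assert len(regions) == 1 and regions[0].n_samples == 5

    def test_single_sample_never_recurrent(self):
        rows = [sv_row("v1", "deletion", "chr2", 1_000_000, pos2=1_010_000),
                sv_row("v2", "deletion", "chr2", 1_050_000, pos2=1_060_000)]
        assert find_recurrent(pd.DataFrame(rows)) == []

    def test_matches_bruteforce_oracle_randomized(self, rng):
        cfg = CascadeConfig(recurrence_window_bp=5_000)
        for _ in range(200):
            rows = []
            for k in range(int(rng.integers(0, 12))):
                rows.append(sv_row(f"v{k}", "deletion", "chr1",
                                   int(rng.integers(0, 100_000)), pos2=None, size=500,
                                   sample=f"s{int(rng.integers(1, 5))}"))
            got = {frozenset(r.sv_ids) for r in find_recurrent(pd.DataFrame(rows, columns=SV_COLS), cfg)} \
                if rows else set()
            want = recurrence_oracle(
                [(r["sv_id"], r["sample_id"], r["chrom1"], r["pos1"]) for r in rows], 5_000)
            assert got == want

    def test_planted_recurrence_recovered(self, zero_noise_cohort):
        t = zero_noise_cohort
        cfg = CascadeConfig(recurrence_window_bp=100_000)
        somatic = t.truth_sv[t.truth_sv.origin == "somatic"]
        annotated = annotate_genes(somatic[SV_COLS], t.genes)
        regions = find_recurrent(annotated, cfg)
        nrx = [r for r in regions if r.dominant_gene == "NRX1L"]
        assert nrx and nrx[0].n_samples >= 2


class TestTally:
    def test_translocation_fraction(self):
        rows = [sv_row(f"d{k}", "deletion", "chr1", 1_000 * k + 10, pos2=1_000 * k + 500)
                for k in range(199)]
        rows.append(sv_row("t1", "translocation", "chr1", 5, "chr2", 5, size=0))
        out = tally(pd.DataFrame(rows))
        frac = dict(zip(out.type, out.fraction))
        assert frac["translocation"] == pytest.approx(0.005)
        assert out.fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_all_zero(self):
        out = tally(sv_frame([]))
        assert (out["count"] == 0).all() and (out.fraction == 0).all()

    def test_generator_counts_match_truth(self, zero_noise_cohort):
        t = zero_noise_cohort
        out = tally(t.sv_tumor)
        planted = t.truth_sv.type.value_counts()
        for _, row in out.iterrows():
            assert row["count"] == planted.get(row["type"], 0)


class TestCascadeConservation:
    def test_counts_conserve_at_every_stage(self, zero_noise_cohort):
        t = zero_noise_cohort
        rare, common = filter_common(t.sv_tumor)
        assert len(rare) + len(common) == len(t.sv_tumor)
        nonpoly, poly = filter_polymorphic(rare, t.catalog)
        assert len(nonpoly) + len(poly) == len(rare)
        sub = nonpoly[nonpoly.sample_id == "S01t"]
        blood = t.sv_blood[t.sv_blood.sample_id == "S01b"]
        somatic, germline = subtract_germline(sub, blood)
        assert len(somatic) + len(germline) == len(sub)
        assert set(somatic.sv_id).isdisjoint(set(germline.sv_id))
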