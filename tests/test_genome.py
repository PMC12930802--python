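"""Interval algebra, genome builds and file-format round-trips."""

import numpy as np
import pandas as pd
import pytest

from _oracles import dice_oracle, intersect_bp_oracle, per_base_mask
from ogmsv import io as gio
from ogmsv.genome import (
    GenomicInterval,
    interval_length,
    intersect_total,
    normalize,
    subtract,
    total_span,
)


class TestIntervals:
    def test_printed_region_sizes(self):
        # sizes are end - start on half-open coordinates
        assert interval_length(GenomicInterval("chr13", 90_684_670, 92_265_557)) == 1_580_887
        assert interval_length(GenomicInterval("chr16", 66_886_992, 69_305_254)) == 2_418_262
        assert interval_length(GenomicInterval("chr1", 5, 6)) == 1

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (7, 3)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_normalize_merges_touching_and_overlapping(self):
        ivs = [GenomicInterval("chr1", 50, 150), GenomicInterval("chr1", 0, 50),
               GenomicInterval("chr1", 200, 300), GenomicInterval("chr2", 10, 20)]
        merged = normalize(ivs)
        assert merged == [GenomicInterval("chr1", 0, 150), GenomicInterval("chr1", 200, 300),
                          GenomicInterval("chr2", 10, 20)]

    def test_intersect_basics(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 50, 150)]
        assert intersect_total(a, b) == 50
        assert intersect_total(a, [GenomicInterval("chr2", 0, 100)]) == 0

    def test_intersect_matches_per_base_oracle_randomized(self, tiny_genome, rng):
        lengths = {c: tiny_genome.lengths[c] for c in tiny_genome.chrom_order}
        for _ in range(300):
            def random_set():
                out = []
                for _ in range(int(rng.integers(0, 12))):
                    chrom = "chr1" if rng.random() < 0.7 else "chr2"
                    start = int(rng.integers(0, lengths[chrom] - 500))
                    out.append(GenomicInterval(chrom, start, start + int(rng.integers(1, 500))))
                return normalize(out)
            a, b = random_set(), random_set()
            expected = intersect_bp_oracle(
                [(iv.chrom, iv.start, iv.end) for iv in a],
                [(iv.chrom, iv.start, iv.end) for iv in b], lengths)
            assert intersect_total(a, b) == expected
            assert intersect_total(b, a) == expected
            assert intersect_total(a, a) == total_span(a)

    def test_subtract_matches_oracle(self, tiny_genome, rng):
        lengths = {c: tiny_genome.lengths[c] for c in tiny_genome.chrom_order}
        for _ in range(100):
            def random_set(n):
                out = []
                for _ in range(n):
                    start = int(rng.integers(0, 99_000))
                    out.append(GenomicInterval("chr1", start, start + int(rng.integers(1, 900))))
                return out
            a, b = random_set(6), random_set(6)
            got = subtract(a, b)
            ma = per_base_mask([(iv.chrom, iv.start, iv.end) for iv in a], lengths)
            mb = per_base_mask([(iv.chrom, iv.start, iv.end) for iv in b], lengths)
            want = ma["chr1"] & ~mb["chr1"]
            mg = per_base_mask([(iv.chrom, iv.start, iv.end) for iv in got], lengths)
            assert (mg["chr1"] == want).all()


class TestCytoband:
    def _write(self, path, rows):
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))

    def test_arms_from_acen(self, tmp_path):
        p = tmp_path / "cyto.txt"
        self._write(p, [
            ("chr1", 0, 40, "p11", "gneg"), ("chr1", 40, 60, "cen", "acen"),
            ("chr1", 60, 100, "q11", "gneg"),
            ("chr2", 0, 20, "p11", "gneg"), ("chr2", 20, 30, "cen", "acen"),
            ("chr2", 30, 80, "q11", "gneg"),
        ])
        build = gio.load_genome(p)
        assert build.chrom_length("chr1") == 100
        assert build.arm("chr1", "p") == GenomicInterval("chr1", 0, 40)
        assert build.arm("chr1", "q") == GenomicInterval("chr1", 60, 100)

    def test_missing_centromere_names_chromosome(self, tmp_path):
        p = tmp_path / "cyto.txt"
        self._write(p, [
            ("chr1", 0, 40, "p11", "gneg"), ("chr1", 40, 60, "cen", "acen"),
            ("chr1", 60, 100, "q11", "gneg"), ("chr2", 0, 80, "p11", "gneg"),
        ])
        with pytest.raises(ValueError, match="no centromere: chr2"):
            gio.load_genome(p)

    def test_out_of_order_bands_equal_sorted(self, tmp_path):
        rows = [
            ("chr1", 60, 100, "q11", "gneg"), ("chr1", 0, 40, "p11", "gneg"),
            ("chr1", 40, 60, "cen", "acen"),
        ]
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        self._write(p1, rows)
        self._write(p2, sorted(rows, key=lambda r: r[1]))
        b1, b2 = gio.load_genome(p1), gio.load_genome(p2)
        assert b1.lengths == b2.lengths and b1.centromeres == b2.centromeres

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "cyto.txt"
        p.write_text("chr1\t0\t40\tp11\tgneg\nchr1\toops\t60\tcen\tacen\n")
        with pytest.raises(ValueError, match="line 2"):
            gio.load_genome(p)


class TestRoundTrips:
    def test_cnv_segments_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "sample_id": ["s1", "s1", "s2"], "chrom": ["chr1", "chr1", "chr2"],
            "start": [0, 5_000, 100], "end": [1_000, 9_000, 900],
            "fract_cn": [2.8, 1.2, 3.9], "confidence": [0.9, 0.8, 0.99],
        })
        p = tmp_path / "cnv.tsv"
        gio.write_cnv_segments(df, p)
        back = gio.read_cnv_segments(p)
        pd.testing.assert_frame_equal(back, df)
        gio.write_cnv_segments(back, tmp_path / "cnv2.tsv")
        assert (tmp_path / "cnv2.tsv").read_bytes() == p.read_bytes()

    def test_seg_log2_conversion(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
                     "s1\tchr1\t0\t1000\t50\t0.5\n")
        df = gio.read_seg_file(p)
        assert df.loc[0, "fract_cn"] == pytest.approx(2 * 2 ** 0.5)

    def test_sv_unknown_type_rejected(self, tmp_path):
        p = tmp_path / "sv.tsv"
        p.write_text("sv_id\tsample_id\ttype\tchrom1\tpos1\tchrom2\tpos2\tsize_bp\tconfidence\tcontrol_af\n"
                     "v1\ts1\tinversion_partial\tchr1\t10\tchr1\t20\t10\t0.9\t\n")
        with pytest.raises(ValueError, match="insertion"):
            gio.read_sv_calls(p)

    def test_sv_round_trip_with_missing_af(self, tmp_path):
        p = tmp_path / "sv.tsv"
        df = pd.DataFrame({
            "sv_id": ["v1", "v2"], "sample_id": ["s1", "s1"],
            "type": ["deletion", "translocation"],
            "chrom1": ["chr1", "chr1"], "pos1": [100, 500],
            "chrom2": ["chr1", "chr2"], "pos2": [200, 700],
            "size_bp": [100, 0], "confidence": [0.9, 0.95],
            "control_af": [0.005, np.nan],
        })
        gio.write_sv_calls(df, p)
        back = gio.read_sv_calls(p)
        pd.testing.assert_frame_equal(back, df)

    def test_fusion_confidence_validated(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("sample_id\tgene1\tgene2\tchrom1\tpos1\tchrom2\tpos2\tconfidence\treading_frame\n"
                     "s1\tA\tB\tchr1\t10\tchr2\t20\tvery-high\t.\n")
        with pytest.raises(ValueError, match="high"):
            gio.read_fusion_calls(p)

    def test_gene_model_round_trip(self, tmp_path):
        from ogmsv.genome import GeneRecord
        genes = [
            GeneRecord("A", GenomicInterval("chr1", 100, 1_000), "+",
                       (GenomicInterval("chr1", 150, 200), GenomicInterval("chr1", 700, 900)),
                       True),
            GeneRecord("B", GenomicInterval("chr2", 0, 500), "-",
                       (GenomicInterval("chr2", 10, 60),), False),
        ]
        p = tmp_path / "genes.bed"
        gio.write_gene_model(genes, p)
        back = gio.read_gene_model(p)
        assert back == genes

    def test_catalog_round_trip(self, tmp_path):
        from ogmsv.genome import CatalogRegion
        regions = [CatalogRegion(GenomicInterval("chr1", 0, 500), 0.05, "control-db"),
                   CatalogRegion(GenomicInterval("chr2", 10, 20), 0.001, "control-db")]
        p = tmp_path / "cat.bed"
        gio.write_catalog(regions, p)
        back = gio.read_catalog(p)
        assert [(r.interval, r.allele_frequency) for r in back] == \
               [(r.interval, r.allele_frequency) for r in regions]
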