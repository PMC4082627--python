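"""Nearest-TSS assignment, distance binning, and context classification."""

import numpy as np
import pytest

from peakscape.annotation import (
    GeneIndex,
    GeneModel,
    annotate_peaks,
    bin_distance,
    classify_context,
    location_summary,
    nearest_tss,
    read_gene_table,
    target_genes,
    top_regions,
    tss_of,
    write_gene_table,
)
from peakscape.intervals import GenomicInterval

from conftest import make_peaks


def gene(gene_id, chrom, strand, start, end, exons=()):
    return GeneModel(gene_id, chrom, strand, start, end, tuple(exons))


class TestTss:
    def test_plus_strand(self):
        assert tss_of(gene("g", "chr1", "+", 1000, 2000)) == 1000

    def test_minus_strand(self):
        assert tss_of(gene("g", "chr1", "-", 1000, 2000)) == 1999

    def test_strand_flip_moves_tss_to_opposite_end(self):
        plus = gene("g", "chr1", "+", 1000, 2000)
        minus = gene("g", "chr1", "-", 1000, 2000)
        assert {tss_of(plus), tss_of(minus)} == {1000, 1999}


class TestNearestTss:
    def test_worked_example(self):
        genes = [gene("g1", "chr1", "+", 1000, 5000),
                 gene("g2", "chr1", "+", 3000, 8000)]
        peak = GenomicInterval("chr1", 1400, 1600)  # center 1500
        gid, d = nearest_tss(peak, genes)
        assert gid == "g1" and d == 500

    def test_peak_on_tss(self):
        genes = [gene("g1", "chr1", "+", 1500, 5000)]
        gid, d = nearest_tss(GenomicInterval("chr1", 1400, 1600), genes)
        assert gid == "g1" and d == 0
        assert bin_distance(d) == "<1kb"

    def test_equidistant_tie_breaks_to_smaller_gene_id(self):
        genes = [gene("gB", "chr1", "+", 3500, 5000),
                 gene("gA", "chr1", "+", 7500, 9000)]
        # center 5500 is 2000 from both TSSs
        gid, _ = nearest_tss(GenomicInterval("chr1", 5400, 5600), genes)
        assert gid == "gA"

    def test_no_gene_on_chromosome_reported_not_raised(self):
        genes = [gene("g1", "chr1", "+", 0, 100)]
        gid, d = nearest_tss(GenomicInterval("chr9", 0, 100), genes)
        assert gid is None and d is None

    def test_upstream_sign_is_strand_aware(self):
        plus = [gene("g1", "chr1", "+", 5000, 9000)]
        minus = [gene("g1", "chr1", "-", 1000, 5000)]
        peak = GenomicInterval("chr1", 3900, 4100)  # center 4000
        _, d_plus = nearest_tss(peak, plus)    # upstream of + TSS at 5000
        assert d_plus == -1000
        _, d_minus = nearest_tss(peak, minus)  # downstream of - TSS at 4999
        assert d_minus == 999

    def test_agrees_with_linear_scan_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            genes = []
            for k in range(int(rng.integers(1, 12))):
                start = int(rng.integers(0, 90_000))
                end = start + int(rng.integers(100, 5_000))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(gene(f"g{k:02d}", "chr1", strand, start, end))
            index = GeneIndex(genes)
            center = int(rng.integers(0, 100_000))
            peak = GenomicInterval("chr1", center, center + 1)
            gid, signed = index.nearest_tss("chr1", center)
            # oracle: exhaustive scan, tie-break on (distance, gene_id)
            best = min(genes, key=lambda g: (abs(center - tss_of(g)), g.gene_id))
            assert gid == best.gene_id
            assert abs(signed) == abs(center - tss_of(best))


class TestBinDistance:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (0, "<1kb"), (500, "<1kb"), (999, "<1kb"),
            (1000, "1-10kb"), (-5000, "1-10kb"), (9999, "1-10kb"),
            (10_000, "10-100kb"), (-99_999, "10-100kb"),
            (100_000, ">100kb"), (250_000, ">100kb"), (None, ">100kb"),
        ],
    )
    def test_boundaries_half_open_absolute(self, d, expected):
        assert bin_distance(d) == expected


class TestContext:
    def setup_method(self):
        # gene on + strand: TSS 10_000, exons at [10_000,10_200) and
        # [14_000,14_300); intron between
        self.genes = [
            gene("g1", "chr1", "+", 10_000, 20_000,
                 exons=[(10_000, 10_200), (14_000, 14_300)])
        ]

    def test_promoter_precedence_over_exon(self):
        # center 500 bp upstream of TSS
        peak = GenomicInterval("chr1", 9_400, 9_600)
        assert classify_context(peak, self.genes) == "promoter"
        # center inside first exon but <1 kb from TSS -> still promoter
        peak2 = GenomicInterval("chr1", 10_050, 10_150)
        assert classify_context(peak2, self.genes) == "promoter"

    def test_intron_beyond_promoter_radius(self):
        peak = GenomicInterval("chr1", 12_900, 13_100)  # center 13_000
        assert classify_context(peak, self.genes) == "intron"

    def test_exon_beyond_promoter_radius(self):
        peak = GenomicInterval("chr1", 14_050, 14_250)  # center 14_150
        assert classify_context(peak, self.genes) == "exon"

    def test_intergenic_far_from_everything(self):
        peak = GenomicInterval("chr1", 60_000, 60_200)
        assert classify_context(peak, self.genes) == "intergenic"

    def test_every_peak_gets_exactly_one_context(self):
        rng = np.random.default_rng(23)
        contexts = {"promoter", "exon", "intron", "intergenic"}
        for _ in range(100):
            c = int(rng.integers(0, 70_000))
            peak = GenomicInterval("chr1", c, c + 100)
            assert classify_context(peak, self.genes) in contexts


class TestLocationSummary:
    def test_all_peaks_at_tss(self):
        genes = [gene("g1", "chr1", "+", 10_000, 20_000)]
        peaks = make_peaks("F", [("chr1", 9_950, 10_050),
                                 ("chr1", 9_900, 10_100)])
        summary = location_summary(peaks, genes)
        assert summary.bin_fractions["<1kb"] == 1.0

    def test_fractions_partition_to_one(self):
        rng = np.random.default_rng(31)
        genes = [gene(f"g{k}", "chr1", "+", int(p), int(p) + 2_000)
                 for k, p in enumerate(rng.integers(0, 500_000, 10))]
        triples = [("chr1", int(s), int(s) + 200)
                   for s in rng.integers(0, 600_000, 50)]
        summary = location_summary(make_peaks("F", triples), genes)
        assert sum(summary.bin_fractions.values()) == pytest.approx(1.0)
        assert sum(summary.context_fractions.values()) == pytest.approx(1.0)

    def test_empty_peaks_rejected(self):
        genes = [gene("g1", "chr1", "+", 0, 100)]
        with pytest.raises(ValueError):
            location_summary(make_peaks("F", []), genes)

    def test_recovers_planted_mix(self, default_bundle):
        """Annotation recovers the generator's TSS-distance mix (±0.03)."""
        from peakscape.intervals import read_bed

        cfg = default_bundle.truth.config
        peaks = read_bed(default_bundle.peak_beds[cfg.factors[0]])
        genes = read_gene_table(default_bundle.gene_table)
        summary = location_summary(peaks, genes)
        for frac, name in zip(cfg.location_mix,
                              ("<1kb", "1-10kb", "10-100kb", ">100kb")):
            assert summary.bin_fractions[name] == pytest.approx(frac, abs=0.03)


class TestTargetGenes:
    def test_distinct_and_multi(self):
        genes = [gene("g1", "chr1", "+", 1_000, 3_000),
                 gene("g2", "chr1", "+", 50_000, 53_000)]
        peaks = make_peaks("F", [("chr1", 900, 1_100),
                                 ("chr1", 2_000, 2_200),
                                 ("chr1", 49_000, 49_400)])
        annos = annotate_peaks(peaks, genes)
        distinct, multi = target_genes(annos)
        assert distinct == {"g1", "g2"}
        assert multi == {"g1"}

    def test_empty(self):
        distinct, multi = target_genes([])
        assert distinct == set() and multi == set()

    def test_counts_match_tally_oracle(self):
        rng = np.random.default_rng(37)
        genes = [gene(f"g{k}", "chr1", "+", int(p), int(p) + 1_000)
                 for k, p in enumerate(rng.integers(0, 200_000, 8))]
        triples = [("chr1", int(s), int(s) + 100)
                   for s in rng.integers(0, 220_000, 40)]
        annos = annotate_peaks(make_peaks("F", triples), genes)
        distinct, multi = target_genes(annos)
        tally: dict[str, int] = {}
        for a in annos:
            tally[a.nearest_gene] = tally.get(a.nearest_gene, 0) + 1
        assert distinct == set(tally)
        assert multi == {g for g, n in tally.items() if n >= 2}


class TestTopRegions:
    def test_n_larger_than_set_returns_full_set(self):
        peaks = make_peaks("F", [("chr1", 0, 100, 5), ("chr1", 200, 300, 1)])
        assert len(top_regions(peaks, 10)) == 2

    def test_single_max(self):
        peaks = make_peaks("F", [("chr1", 0, 100, 5), ("chr1", 200, 300, 9)])
        top = top_regions(peaks, 1)
        assert len(top) == 1 and top[0].score == 9

    def test_stable_under_permutation(self):
        rng = np.random.default_rng(41)
        rows = [("chr1", i * 500, i * 500 + 100, float(s))
                for i, s in enumerate(rng.integers(0, 5, 20))]
        a = make_peaks("F", rows)
        b = make_peaks("F", [rows[i] for i in rng.permutation(20)])
        assert top_regions(a, 7).intervals == top_regions(b, 7).intervals


class TestGeneTableIO:
    def test_round_trip(self, tmp_path):
        genes = [
            gene("g1", "chr1", "+", 100, 5_000, exons=[(100, 300), (4_000, 4_500)]),
            gene("g2", "chr2", "-", 0, 900),
        ]
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        assert read_gene_table(path) == genes

    def test_invalid_exons_named_with_line(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("g1\tchr1\t+\t100\t500\t50,\t80,\n")
        with pytest.raises(ValueError, match=":1"):
            read_gene_table(path)
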