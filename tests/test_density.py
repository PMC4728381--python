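import math

import pytest

import hmcpeaks as h
from hmcpeaks.density import DensityRow, round_half_up

from _oracles import assign_peak_oracle, per_base_masks


def peak(contig, start, end):
    return h.Peak(h.GenomicInterval(contig, start, end))


@pytest.fixture(scope="module")
def one_gene_map():
    # gene with exon/intron structure and full flank clearance
    gene = h.GeneModel(
        "g1",
        h.GenomicInterval("ctg1", 20_000, 21_000, "+"),
        (
            h.GenomicInterval("ctg1", 20_000, 20_300, "+"),
            h.GenomicInterval("ctg1", 20_700, 21_000, "+"),
        ),
    )
    contigs = h.ContigCatalog({"ctg1": 60_000})
    return h.build_element_map([gene], contigs)


class TestAssignPeak:
    def test_exonic_peak(self, one_gene_map):
        assert h.assign_peak(peak("ctg1", 20_100, 20_200), one_gene_map) == {
            "CDS_Exons"
        }

    def test_junction_peak_is_exonic(self, one_gene_map):
        # spans exon/intron boundary; exonic priority wins
        assert h.assign_peak(peak("ctg1", 20_250, 20_350), one_gene_map) == {
            "CDS_Exons"
        }

    def test_intronic_peak(self, one_gene_map):
        assert h.assign_peak(peak("ctg1", 20_400, 20_500), one_gene_map) == {
            "Introns"
        }

    def test_upstream_peak_hits_all_nested_windows(self, one_gene_map):
        got = h.assign_peak(peak("ctg1", 19_650, 19_700), one_gene_map)
        assert got == {"TSS_up_1kb", "TSS_up_5kb", "TSS_up_10kb"}

    def test_far_upstream_peak_hits_outer_windows_only(self, one_gene_map):
        got = h.assign_peak(peak("ctg1", 15_500, 15_600), one_gene_map)
        assert got == {"TSS_up_5kb", "TSS_up_10kb"}

    def test_intergenic_peak_unassigned(self, one_gene_map):
        assert h.assign_peak(peak("ctg1", 2_000, 2_100), one_gene_map) == set()

    def test_unknown_contig(self, one_gene_map):
        with pytest.raises(h.ValidationError):
            h.assign_peak(peak("ctgX", 0, 10), one_gene_map)

    def test_midpoint_criterion(self, one_gene_map):
        p = peak("ctg1", 20_290, 20_500)  # 10 bp exon overlap, midpoint intronic
        assert h.assign_peak(p, one_gene_map, "overlap") == {"CDS_Exons"}
        assert h.assign_peak(p, one_gene_map, "midpoint") == {"Introns"}

    def test_matches_per_base_oracle(self, sim_genome, sim_peaks, sim_element_map):
        genes, contigs = sim_genome
        masks = per_base_masks(genes, contigs)
        for p in sim_peaks[::7]:
            assert h.assign_peak(p, sim_element_map) == assign_peak_oracle(
                p, masks
            )


TABLE_PUBLISHED = [
    # (element, total_bases, tag_count, printed tags/kb)
    ("CDS_Exons", 17_597_397, 10_651, 0.61),
    ("Introns", 17_376_020, 4_652, 0.27),
    ("TSS_up_1kb", 12_615_965, 1_012, 0.08),
    ("TSS_up_5kb", 35_083_848, 2_304, 0.07),
    ("TSS_up_10kb", 57_615_402, 2_585, 0.04),
    ("TES_down_1kb", 11_356_574, 1_191, 0.10),
    ("TES_down_5kb", 31_789_833, 2_351, 0.07),
    ("TES_down_10kb", 53_166_077, 2_506, 0.05),
]


class TestDensityArithmetic:
    @pytest.mark.parametrize(
        "element,total_bases,tags,expected",
        TABLE_PUBLISHED,
        ids=[r[0] for r in TABLE_PUBLISHED],
    )
    def test_published_density_values(self, element, total_bases, tags, expected):
        row = DensityRow.from_counts(element, total_bases, tags)
        assert row.tags_per_kb == expected

    def test_rounding_is_half_up(self):
        # 45 tags over 1 Mb is exactly 0.045/kb; half-up gives 0.05
        assert DensityRow.from_counts("x", 1_000_000, 45).tags_per_kb == 0.05
        assert round_half_up(0.125, 2) == 0.13

    def test_zero_peaks(self, one_gene_map):
        table = h.density_table([], one_gene_map)
        assert all(r.tag_count == 0 for r in table.rows)
        assert all(r.tags_per_kb == 0.0 for r in table.rows)

    def test_empty_map_rejected(self):
        emap = h.ElementMap({}, {}, h.ContigCatalog({"c": 10}))
        with pytest.raises(h.ValidationError):
            h.density_table([], emap)


class TestDensityTable:
    def test_row_order_and_unassigned(self, one_gene_map):
        peaks = [peak("ctg1", 2_000, 2_050), peak("ctg1", 20_100, 20_150)]
        table = h.density_table(peaks, one_gene_map)
        assert [r.element for r in table.rows] == list(h.ELEMENT_CLASSES)
        assert table.n_peaks_input == 2
        assert table.n_peaks_unassigned == 1

    def test_nested_counts_monotone(self, sim_peaks, sim_element_map):
        table = h.density_table(sim_peaks, sim_element_map)
        count = {r.element: r.tag_count for r in table.rows}
        for side in ("TSS_up", "TES_down"):
            assert (
                count[f"{side}_1kb"]
                <= count[f"{side}_5kb"]
                <= count[f"{side}_10kb"]
            )

    def test_each_peak_counted_and_genic_exclusive(
        self, sim_peaks, sim_element_map
    ):
        n_exon = n_intron = n_outer = 0
        for p in sim_peaks:
            classes = h.assign_peak(p, sim_element_map)
            assert not ({"CDS_Exons", "Introns"} <= classes)
            n_exon += "CDS_Exons" in classes
            n_intron += "Introns" in classes
            n_outer += bool(classes & {"TSS_up_10kb", "TES_down_10kb"})
        table = h.density_table(sim_peaks, sim_element_map)
        covered = n_exon + n_intron + n_outer + table.n_peaks_unassigned
        assert covered >= len(sim_peaks)

    def test_disjoint_counting_uses_smallest_window(self, one_gene_map):
        p = peak("ctg1", 19_650, 19_700)  # inside the 1 kb upstream window
        cumulative = h.density_table([p], one_gene_map)
        disjoint = h.density_table([p], one_gene_map, window_counting="disjoint")
        cum = {r.element: r.tag_count for r in cumulative.rows}
        dis = {r.element: r.tag_count for r in disjoint.rows}
        assert cum["TSS_up_1kb"] == cum["TSS_up_5kb"] == cum["TSS_up_10kb"] == 1
        assert dis["TSS_up_1kb"] == 1
        assert dis["TSS_up_5kb"] == dis["TSS_up_10kb"] == 0


class TestExonIntronRatio:
    def _table(self, exon_counts, intron_counts):
        rows = [
            DensityRow.from_counts("CDS_Exons", *exon_counts),
            DensityRow.from_counts("Introns", *intron_counts),
        ]
        return h.DensityTable(rows, 0, 0)

    def test_published_counts_give_ratio_2_26(self):
        table = self._table((17_597_397, 10_651), (17_376_020, 4_652))
        assert round(h.exon_intron_ratio(table), 2) == 2.26

    def test_equal_densities(self):
        assert h.exon_intron_ratio(self._table((1000, 5), (1000, 5))) == 1.0

    def test_zero_exon_tags(self):
        assert h.exon_intron_ratio(self._table((1000, 0), (1000, 5))) == 0.0

    def test_zero_intron_density_undefined(self):
        with pytest.raises(h.ValidationError):
            h.exon_intron_ratio(self._table((1000, 5), (1000, 0)))
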