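"""SV filtering, window overlap, association statistics and promoter
cis-element scanning."""


import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panfam import sv
from panfam.simulate import write_sv_vcf


def make_sv(chrom="chr1", pos=100, ref_len=1, alt_len=200,
            presence=None, depth=None):
    presence = presence if presence is not None else {"A": True, "B": False}
    depth = depth if depth is not None else {g: 30 for g in presence}
    return sv.StructuralVariant(chrom, pos, ref_len, alt_len, presence, depth)


class TestTypeAndFilter:
    @pytest.mark.parametrize(
        "ref_len,alt_len,expected",
        [(1, 350, "insertion"), (500, 1, "deletion"), (5, 5, "other")],
    )
    def test_type_by_allele_lengths(self, ref_len, alt_len, expected):
        assert sv.classify_sv_type(ref_len, alt_len) == expected

    def test_depth_exactly_twenty_is_retained(self):
        rec = make_sv(presence={"A": True}, depth={"A": 20})
        assert len(sv.filter_svs([rec], 20)) == 1

    def test_depth_nineteen_everywhere_drops_record(self):
        rec = make_sv(presence={"A": True, "B": True}, depth={"A": 19, "B": 19})
        assert sv.filter_svs([rec], 20) == []

    def test_mixed_depth_keeps_only_qualified_carrier(self):
        rec = make_sv(presence={"A": True, "B": True}, depth={"A": 25, "B": 10})
        (kept,) = sv.filter_svs([rec], 20)
        assert kept.carriers == {"A"}

    def test_vcf_round_trip(self, tmp_path):
        records = [
            make_sv("chr1", 500, 300, 1, {"A": True, "B": False}, {"A": 25, "B": 18}),
            make_sv("chr2", 900, 1, 120, {"A": False, "B": True}, {"A": 40, "B": 33}),
        ]
        path = tmp_path / "svs.vcf"
        write_sv_vcf(path, records, ["A", "B"])
        back = sv.read_sv_vcf(path)
        assert [(r.chrom, r.pos, r.sv_type) for r in back] == [
            ("chr1", 500, "deletion"), ("chr2", 900, "insertion")
        ]
        assert back[0].presence == {"A": True, "B": False}
        assert back[0].depth == {"A": 25, "B": 18}


class TestOverlap:
    window = sv.GeneWindow.from_gene("g", "chr1", 5000, 8000, flank=2000)

    def test_window_spans_gene_plus_flanks(self):
        assert (self.window.start, self.window.end) == (3000, 10000)

    def test_deletion_inside_window(self):
        assert sv.overlaps(make_sv(pos=9500, ref_len=301, alt_len=1), self.window)

    def test_insertion_at_window_boundary(self):
        assert not sv.overlaps(make_sv(pos=2999, ref_len=1, alt_len=50), self.window)
        assert sv.overlaps(make_sv(pos=3000, ref_len=1, alt_len=50), self.window)

    def test_deletion_straddling_window_start(self):
        assert sv.overlaps(make_sv(pos=1000, ref_len=2501, alt_len=1), self.window)

    def test_other_chromosome_never_overlaps(self):
        assert not sv.overlaps(make_sv(chrom="chr9", pos=5000), self.window)

    def test_zero_flank_reduces_to_gene_body(self):
        w0 = sv.GeneWindow.from_gene("g", "chr1", 5000, 8000, flank=0)
        assert not sv.overlaps(make_sv(pos=4000, ref_len=1, alt_len=9), w0)
        assert sv.overlaps(make_sv(pos=5000, ref_len=1, alt_len=9), w0)


class TestAssociation:
    def test_closed_form_point_biserial(self):
        res = sv.associate([0, 0, 1, 1], [1, 2, 3, 4])
        assert res.correlation.r == pytest.approx(2 / np.sqrt(5))

    def test_constant_presence_is_na(self):
        res = sv.associate([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.correlation.defined
        assert res.correlation.reason == "constant_input"
        assert not res.significant

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sv.associate([0, 1], [1, 2, 3])

    def test_p_equals_two_sample_t_test(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            presence = np.array([0] * 6 + [1] * 6)
            rng.shuffle(presence)
            expr = rng.normal(10, 3, size=12)
            res = sv.associate(presence, expr)
            t = stats.ttest_ind(expr[presence == 1], expr[presence == 0])
            assert res.correlation.p == pytest.approx(t.pvalue, abs=1e-10)


class TestPromoter:
    def test_plus_strand_promoter_coordinates(self):
        chrom = "".join("ACGT"[i % 4] for i in range(6000))
        prom = sv.extract_promoter(chrom, 3001, 4000, "+", length=2000)
        assert prom == chrom[1000:3000]

    def test_minus_strand_promoter_reverse_complemented(self):
        chrom = "A" * 400 + "C" * 100 + "G" * 2000 + "A" * 2500
        prom = sv.extract_promoter(chrom, 101, 500, "-", length=2000)
        # bases 501..2500 are all G; reverse complement is all C
        assert prom == "C" * 2000

    def test_truncation_at_contig_start_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            prom = sv.extract_promoter("ACGT" * 100, 100, 200, "+", length=2000)
        assert len(prom) == 99

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            sv.extract_promoter("ACGT", 2, 3, ".")


class TestMotifScan:
    def test_simple_motif_count(self):
        assert sv.count_motif("CCTATACC", "TATA") == 1

    def test_palindrome_counted_once_per_position(self):
        assert sv.count_motif("AACACGTGAA", "CACGTG") == 1

    def test_reverse_strand_occurrence_found(self):
        # TTGACC reverse-complement is GGTCAA
        assert sv.count_motif("AAGGTCAAAA", "TTGACC") == 1

    def test_iupac_degeneracy(self):
        assert sv.count_motif("ATACGTGG", "ACGTGK") == 1

    def test_invalid_iupac_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            sv.count_motif("ACGT", "AXGT")

    def test_empty_promoter_set_gives_empty_table(self):
        motifs = pd.DataFrame(
            [("TATA-box", "TATA", "growth")], columns=["name", "pattern", "category"]
        )
        table = sv.compare_elements({}, {}, motifs)
        assert table.empty

    def test_counts_and_category_rollup(self):
        motifs = pd.DataFrame(
            [("TATA-box", "TATA", "growth"), ("W-box", "TTGACC", "stress")],
            columns=["name", "pattern", "category"],
        )
        table = sv.compare_elements(
            {"p1": "CCTATACC"}, {"q1": "TTGACCTATA"}, motifs,
            label_a="HD", label_b="TGY",
        )
        row = table.set_index("element")
        assert row.loc["TATA-box", "HD"] == 1
        assert row.loc["TATA-box", "TGY"] == 1
        assert row.loc["W-box", "HD"] == 0
        rollup = sv.category_rollup(table, "HD", "TGY")
        stress = rollup.set_index("category")
        assert stress.loc["stress", "TGY"] == 1
        assert stress.loc["stress", "HD"] == 0

    def test_empty_motif_table_rejected(self):
        with pytest.raises(ValueError, match="motif"):
            sv.compare_elements({}, {}, pd.DataFrame())


def test_gene_presence_matrix_unions_overlapping_svs(bundle, sv_bundle):
    filtered = sv.filter_svs(sv_bundle.svs, 20)
    genes = bundle.genes[bundle.genes["genome"] == bundle.genomes[0]]
    windows = [
        sv.GeneWindow.from_gene(r.gene_id, r.chrom, r.start, r.end, 2000)
        for r in genes.itertuples()
    ]
    presence = sv.gene_sv_presence(filtered, windows, bundle.genomes)
    # brute-force check on a handful of genes
    for w in windows[:10]:
        expected = set()
        for rec in filtered:
            if sv.overlaps(rec, w):
                expected |= rec.carriers
        got = set(presence.columns[presence.loc[w.gene_id] == 1])
        assert got == expected
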