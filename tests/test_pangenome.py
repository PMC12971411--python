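"""Occupancy categories, membership matrix, PAV and saturation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panfam import pangenome
from panfam.io import read_orthogroups


def long_table(rows):
    return pd.DataFrame(rows, columns=["og", "genome", "gene_id"])


class TestCategoryRule:
    @pytest.mark.parametrize(
        "occupancy,expected",
        [
            (22, "core"),
            (21, "soft-core"),
            (20, "soft-core"),
            (19, "dispensable"),
            (2, "dispensable"),
            (1, "private"),
        ],
    )
    def test_printed_boundaries_at_22_genomes(self, occupancy, expected):
        assert pangenome.classify_og(occupancy, 22) == expected

    def test_out_of_range_occupancy_rejected(self):
        with pytest.raises(ValueError):
            pangenome.classify_og(0, 22)
        with pytest.raises(ValueError):
            pangenome.classify_og(23, 22)

    def test_single_genome_degenerate_case_reports_core(self):
        with pytest.warns(UserWarning, match="core and private"):
            assert pangenome.classify_og(1, 1) == "core"

    @settings(derandomize=True, max_examples=200)
    @given(n=st.integers(2, 40), occ=st.integers(1, 40))
    def test_every_occupancy_gets_exactly_one_category(self, n, occ):
        if occ > n:
            return
        assert pangenome.classify_og(occ, n) in pangenome.CATEGORIES


class TestMembership:
    def test_single_gene_single_genome(self):
        m = pangenome.build_membership(long_table([("og1", "A", "g1")]), {"g1"})
        assert m.shape == (1, 1) and m.iloc[0, 0] == 1

    def test_copy_counting_per_genome(self):
        table = long_table(
            [("og1", "A", "g1"), ("og1", "A", "g2"), ("og1", "B", "g3")]
        )
        m = pangenome.build_membership(table, {"g1", "g2", "g3"})
        assert list(m.loc["og1", ["A", "B"]]) == [2, 1]

    def test_family_gene_missing_from_table_is_an_error(self):
        with pytest.raises(ValueError, match="ghost"):
            pangenome.build_membership(long_table([("og1", "A", "g1")]), {"g1", "ghost"})

    def test_bundle_membership_matches_truth_copy_counts(self, bundle):
        fam = {g for g, f in bundle.truth.gene_family.items() if f}
        m = pangenome.build_membership(bundle.og_table, fam, genomes=bundle.genomes)
        by_count = bundle.genes[bundle.genes["gene_id"].isin(fam)].groupby(
            ["og", "genome"]
        ).size()
        for (og, genome), count in by_count.items():
            assert m.loc[og, genome] == count


class TestPav:
    def test_binarization(self):
        m = pangenome.build_membership(
            long_table([("og1", "A", f"g{i}") for i in range(3)]), {"g0", "g1", "g2"}
        )
        assert pangenome.pav_matrix(m).iloc[0, 0] == 1

    def test_all_core_input_with_flag_is_empty(self):
        table = long_table([("og1", g, f"x{g}") for g in "AB"])
        m = pangenome.build_membership(table, {"xA", "xB"})
        assert pangenome.pav_matrix(m, exclude_core=True).empty

    def test_bundle_pav_row_count_excludes_planted_core(self, bundle):
        fam = {g for g, f in bundle.truth.gene_family.items() if f}
        m = pangenome.build_membership(bundle.og_table, fam, genomes=bundle.genomes)
        n_core = sum(1 for c in bundle.truth.og_category.values() if c == "core")
        pav = pangenome.pav_matrix(m, exclude_core=True)
        assert len(pav) == len(m) - n_core


class TestSaturation:
    @staticmethod
    def toy_membership():
        rows = [("o1", "A", "a1"), ("o2", "A", "a2"), ("o2", "B", "b1"),
                ("o3", "B", "b2"), ("o2", "C", "c1")]
        return pangenome.build_membership(long_table(rows), {r[2] for r in rows})

    def test_exhaustive_three_genome_expectations(self):
        # brute-force oracle over all 3! genome orders
        sets = {"A": {"o1", "o2"}, "B": {"o2", "o3"}, "C": {"o2"}}
        pans, cores = [], []
        for order in itertools.permutations("ABC"):
            pan, core = [], []
            for k in range(1, 4):
                chosen = [sets[g] for g in order[:k]]
                pan.append(len(set().union(*chosen)))
                core.append(len(set.intersection(*chosen)))
            pans.append(pan)
            cores.append(core)
        expected_pan_k1 = np.mean([p[0] for p in pans])
        assert expected_pan_k1 == pytest.approx(5 / 3)
        assert all(c[2] == 1 for c in cores)

        curve = pangenome.saturation(self.toy_membership(), n_perms=500, seed=0)
        assert curve.pan_mean[0] == pytest.approx(expected_pan_k1, abs=0.1)
        assert curve.core_mean[2] == 1.0
        assert curve.pan_mean[2] == 3.0  # union is order-free

    def test_sampled_orders_match_set_oracle_exactly(self):
        m = self.toy_membership()
        curve = pangenome.saturation(m, n_perms=50, seed=3)
        presence = (m.to_numpy() > 0)
        for pan_row, core_row in zip(curve.per_perm_pan, curve.per_perm_core):
            assert pan_row[-1] == presence.any(axis=1).sum()
            assert core_row[-1] == presence.all(axis=1).sum()

    def test_monotone_per_permutation(self, bundle):
        fam = {g for g, f in bundle.truth.gene_family.items() if f}
        m = pangenome.build_membership(bundle.og_table, fam, genomes=bundle.genomes)
        curve = pangenome.saturation(m, n_perms=25, seed=1)
        assert (np.diff(curve.per_perm_pan, axis=1) >= 0).all()
        assert (np.diff(curve.per_perm_core, axis=1) <= 0).all()
        # k=1: sampling one genome, pan == core
        assert (curve.per_perm_pan[:, 0] == curve.per_perm_core[:, 0]).all()


class TestPerGenomeCounts:
    def test_copies_counted_not_orthogroups(self):
        table = long_table(
            [("og1", "A", "g1"), ("og1", "A", "g2"), ("og1", "B", "g3")]
        )
        m = pangenome.build_membership(table, {"g1", "g2", "g3"})
        tally = pangenome.per_genome_category_counts(m)
        assert tally.loc["A", "core"] == 2
        assert tally.loc["B", "core"] == 1

    def test_absent_genome_contributes_zero(self):
        table = long_table([("og1", "A", "g1"), ("og2", "A", "g2"), ("og2", "B", "g3")])
        m = pangenome.build_membership(table, {"g1", "g2", "g3"})
        tally = pangenome.per_genome_category_counts(m)
        assert tally.loc["B", "private"] == 0

    def test_bundle_totals_match_gene_counts(self, bundle):
        fam = {g for g, f in bundle.truth.gene_family.items() if f}
        m = pangenome.build_membership(bundle.og_table, fam, genomes=bundle.genomes)
        tally = pangenome.per_genome_category_counts(m)
        per_genome = bundle.genes[bundle.genes["gene_id"].isin(fam)].groupby(
            "genome"
        ).size()
        for genome, total in per_genome.items():
            assert tally.loc[genome].sum() == total


def test_orthogroups_reader_handles_empty_cells(tmp_path):
    path = tmp_path / "og.tsv"
    path.write_text("Orthogroup\tA\tB\nog1\tg1, g2\t\nog2\t\tg3\n")
    long = read_orthogroups(path)
    assert len(long) == 3
    assert set(long[long["og"] == "og1"]["gene_id"]) == {"g1", "g2"}
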