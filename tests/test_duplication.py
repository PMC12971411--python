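"""Gene ranking, collinearity chaining and the duplication cascade."""


import numpy as np
import pandas as pd
import pytest

from panfam import duplication as dup


def positions_frame(rows):
    frame = pd.DataFrame(
        rows, columns=["gene_id", "genome", "chrom", "start", "end", "strand"]
    )
    return dup.rank_genes(frame)


def two_sided_positions(n_a=30, n_b=30):
    rows = [(f"A{i}", "X", "cA", 100 * i, 100 * i + 50, "+") for i in range(1, n_a + 1)]
    rows += [(f"B{i}", "X", "cB", 100 * i, 100 * i + 50, "+") for i in range(1, n_b + 1)]
    return positions_frame(rows)


class TestRanks:
    def test_single_gene_gets_rank_one(self):
        pos = positions_frame([("g1", "X", "c1", 500, 900, "+")])
        assert pos.loc[0, "rank"] == 1

    def test_ranks_follow_ascending_start(self):
        pos = positions_frame(
            [("a", "X", "c1", 500, 600, "+"), ("b", "X", "c1", 100, 200, "+"),
             ("c", "X", "c1", 900, 950, "+")]
        )
        ranks = dict(zip(pos["gene_id"], pos["rank"]))
        assert ranks == {"b": 1, "a": 2, "c": 3}

    def test_chromosomes_ranked_independently(self):
        pos = positions_frame(
            [("a", "X", "c1", 500, 600, "+"), ("b", "X", "c2", 900, 950, "+")]
        )
        assert set(pos["rank"]) == {1}

    def test_duplicate_records_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            positions_frame(
                [("a", "X", "c1", 500, 600, "+"), ("a", "X", "c1", 500, 600, "+")]
            )


class TestChainCollinear:
    def test_below_min_block_size_yields_nothing(self):
        pos = two_sided_positions()
        pairs = [(f"A{i}", f"B{i + 10}") for i in range(1, 5)]  # 4 anchors
        assert dup.chain_collinear(pairs, pos, min_block_size=5) == []

    def test_five_parallel_anchors_form_one_block(self):
        pos = two_sided_positions()
        pairs = [(f"A{i}", f"B{i + 10}") for i in range(1, 6)]
        blocks = dup.chain_collinear(pairs, pos, min_block_size=5, max_gap=25)
        assert len(blocks) == 1 and blocks[0].score == 5

    def test_antiparallel_block_allowed(self):
        pos = two_sided_positions()
        pairs = [(f"A{i}", f"B{16 - i}") for i in range(1, 6)]
        blocks = dup.chain_collinear(pairs, pos, min_block_size=5, max_gap=25)
        assert len(blocks) == 1 and blocks[0].score == 5

    def test_large_rank_gap_breaks_chain(self):
        pos = two_sided_positions()
        pairs = [("A1", "B1"), ("A2", "B2"), ("A3", "B3"), ("A4", "B4"), ("A30", "B30")]
        blocks = dup.chain_collinear(pairs, pos, min_block_size=5, max_gap=25)
        assert blocks == []

    @staticmethod
    def oracle_best_chain(anchors, max_gap):
        """Exhaustive search: longest valid chain over all subsets."""
        order = sorted(anchors, key=lambda a: (a[0], a[1]))
        best = 0
        n = len(order)
        for mask in range(1, 1 << n):
            chosen = [order[i] for i in range(n) if mask >> i & 1]
            for direction in (1, -1):
                ok = True
                for (r1, s1), (r2, s2) in zip(chosen, chosen[1:]):
                    if not (r1 < r2 <= r1 + max_gap):
                        ok = False
                        break
                    ds = (s2 - s1) * direction
                    if not (0 < ds <= max_gap):
                        ok = False
                        break
                if ok:
                    best = max(best, len(chosen))
                    break
        return best

    def test_chainer_matches_exhaustive_oracle_on_small_sets(self):
        rng = np.random.default_rng(11)
        pos = two_sided_positions()
        for _ in range(25):
            n = int(rng.integers(3, 9))
            ranks = rng.choice(29, size=(n, 2), replace=False) + 1
            anchors = [(int(r), int(s)) for r, s in ranks]
            pairs = [(f"A{r}", f"B{s}") for r, s in anchors]
            max_gap = int(rng.choice([3, 6, 12]))
            blocks = dup.chain_collinear(pairs, pos, min_block_size=1, max_gap=max_gap)
            found = max((b.score for b in blocks), default=0)
            assert found == self.oracle_best_chain(anchors, max_gap)


class TestCascade:
    @staticmethod
    def toy():
        rows = [(f"g{i}", "X", "c1", 1000 * i, 1000 * i + 500, "+") for i in range(1, 13)]
        rows += [(f"h{i}", "X", "c2", 1000 * i, 1000 * i + 500, "+") for i in range(1, 13)]
        return positions_frame(rows)

    def test_block_anchor_beats_adjacency(self):
        # an anchor pair that is also rank-adjacent stays WGD (priority)
        pos = self.toy()
        pairs = [(f"g{i}", f"h{i}") for i in range(1, 6)] + [("g1", "g2")]
        blocks = dup.chain_collinear(pairs, pos, min_block_size=5, max_gap=25)
        calls = {
            frozenset((p.gene_a, p.gene_b)): p.mode
            for p in dup.classify_duplications(pairs, blocks, [], pos)
        }
        assert calls[frozenset(("g1", "h1"))] == "WGD"
        assert calls[frozenset(("g1", "g2"))] == "TD"

    def test_cascade_modes_on_toy_genome(self):
        pos = self.toy()
        outgroup_rows = [(f"o{i}", "OUT", "cO", 1000 * i, 1000 * i + 500, "+")
                         for i in range(1, 7)]
        all_pos = dup.rank_genes(
            pd.concat(
                [self.toy(), pd.DataFrame(
                    outgroup_rows,
                    columns=["gene_id", "genome", "chrom", "start", "end", "strand"],
                )],
                ignore_index=True,
            )
        )
        # outgroup block anchored at g1..g6
        outgroup_pairs = [(f"g{i}", f"o{i}") for i in range(1, 7)]
        out_blocks = dup.chain_collinear(outgroup_pairs, all_pos, 5, 25)
        assert len(out_blocks) == 1

        pairs = [("g1", "g2"),   # rank distance 1 -> TD
                 ("g3", "g10"),  # rank distance 7 -> PD
                 ("g4", "h12"),  # cross-chromosome, g4 outgroup-anchored -> TRD
                 ("h1", "h12")]  # distance 11 > pd_max_gap, no anchors -> DSD
        calls = {
            frozenset((p.gene_a, p.gene_b)): p.mode
            for p in dup.classify_duplications(pairs, [], out_blocks, all_pos)
        }
        assert calls[frozenset(("g1", "g2"))] == "TD"
        assert calls[frozenset(("g3", "g10"))] == "PD"
        assert calls[frozenset(("g4", "h12"))] == "TRD"
        assert calls[frozenset(("h1", "h12"))] == "DSD"

    def test_cross_genome_pair_rejected(self):
        rows = [("a", "X", "c1", 100, 200, "+"), ("b", "Y", "c1", 100, 200, "+")]
        pos = positions_frame(rows)
        with pytest.raises(ValueError, match="spans genomes"):
            dup.classify_duplications([("a", "b")], [], [], pos)

    def test_every_pair_gets_exactly_one_mode(self, bundle, bundle_mode_calls):
        assert len(bundle_mode_calls) == len(bundle.truth.pair_mode)
        assert all(mode in dup.MODES for mode in bundle_mode_calls.values())

    def test_removing_blocks_only_moves_pairs_down_the_cascade(self, bundle):
        from panfam import pipeline

        positions = dup.rank_genes(bundle.genes)
        params = dict(pipeline.DEFAULT_PARAMS)
        by_genome = pipeline._candidate_pairs(bundle.self_hits, positions, params)
        pairs = [p for ps in by_genome.values() for p in ps]
        blocks = dup.chain_collinear(pairs, positions, 5, 25)
        with_blocks = {
            p.pair: p.mode for p in dup.classify_duplications(pairs, blocks, [], positions)
        }
        without = {
            p.pair: p.mode for p in dup.classify_duplications(pairs, [], [], positions)
        }
        for key, mode in with_blocks.items():
            assert dup.MODE_PRIORITY[without[key]] >= dup.MODE_PRIORITY[mode]


def test_bundle_modes_recover_planted_truth(bundle, bundle_mode_calls):
    for pair, mode in bundle.truth.pair_mode.items():
        assert bundle_mode_calls[pair] == mode, (sorted(pair), mode)


class TestCrosstab:
    def test_single_wgd_pair_is_all_wgd(self):
        pairs = [dup.DuplicationPair("a", "b", "WGD", "")]
        table, shares = dup.crosstab_mode_by_category(
            pairs, {"a": "og1", "b": "og1"}, {"og1": "core"}
        )
        assert shares["WGD"] == 100.0
        assert table.loc["WGD", "core"] == 1

    def test_printed_mode_counts_give_printed_shares(self):
        counts = {"WGD": 783, "TRD": 656, "PD": 513, "TD": 236, "DSD": 123}
        pairs = [
            dup.DuplicationPair(f"a{m}{i}", f"b{m}{i}", m, "")
            for m, n in counts.items() for i in range(n)
        ]
        og_of = {g: "og1" for p in pairs for g in (p.gene_a, p.gene_b)}
        table, shares = dup.crosstab_mode_by_category(pairs, og_of, {"og1": "core"})
        assert int(table.to_numpy().sum()) == 2311
        assert shares.to_dict() == {
            "WGD": 33.9, "TD": 10.2, "PD": 22.2, "TRD": 28.4, "DSD": 5.3
        }

    def test_per_gene_summary_takes_highest_priority_mode(self):
        pairs = [dup.DuplicationPair("a", "b", "DSD", ""),
                 dup.DuplicationPair("a", "c", "WGD", "")]
        assert dup.per_gene_modes(pairs)["a"] == "WGD"
        assert dup.per_gene_modes(pairs)["b"] == "DSD"
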