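"""Block chaining vs exhaustive oracle, tandem rule, depth, spans, dot plots."""

import numpy as np
import pandas as pd
import pytest

from paleodup.homology import HomologPair, make_pair
from paleodup.synteny import (
    Anchor,
    anchors_from_pairs,
    chain_blocks,
    classify_tandem,
    colocalization_span,
    dotplot_table,
    restrict_to_blocks,
    synteny_depth,
)
from paleodup.synthetic_data import SimConfig, depth_to_mya, simulate

from _oracles import best_chain_oracle
from conftest import toy_genome


def mk_anchor(r1, r2, c1="chr1", c2="chr2", tag=""):
    return Anchor(HomologPair(f"a{r1}{tag}", f"b{r2}{tag}"), c1, r1, c2, r2)


class TestChainBlocks:
    def test_perfect_diagonal(self):
        anchors = [mk_anchor(i, i) for i in range(6)]
        (block,) = chain_blocks(anchors, max_gap=25, min_block=5)
        assert block.score == 6 and block.orientation == "same"

    def test_antidiagonal_inverted(self):
        anchors = [mk_anchor(i, 5 - i) for i in range(6)]
        (block,) = chain_blocks(anchors, max_gap=25, min_block=5)
        assert block.score == 6 and block.orientation == "inverted"

    def test_short_chains_discarded(self):
        anchors = [mk_anchor(i, i) for i in range(4)]
        assert chain_blocks(anchors, min_block=5) == []

    def test_gap_constraint_splits_chain(self):
        anchors = [mk_anchor(i, i) for i in range(5)] + [
            mk_anchor(i + 100, i + 100) for i in range(5)
        ]
        blocks = chain_blocks(anchors, max_gap=25, min_block=5)
        assert len(blocks) == 2 and all(b.score == 5 for b in blocks)

    def test_blocks_monotone_on_both_axes(self, rng):
        anchors = [
            mk_anchor(int(r1), int(r2))
            for r1, r2 in {tuple(rng.integers(0, 40, 2)) for _ in range(60)}
        ]
        for block in chain_blocks(anchors, max_gap=25, min_block=2):
            r1 = [a.rank1 for a in block.anchors]
            r2 = [a.rank2 for a in block.anchors]
            assert r1 == sorted(r1) and len(set(r1)) == len(r1)
            sgn = 1 if block.orientation == "same" else -1
            assert all(sgn * (y - x) > 0 for x, y in zip(r2, r2[1:]))

    @pytest.mark.parametrize("seed", range(12))
    def test_best_chain_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(8, 15))
        perm = rng.permutation(n)
        points = [(i, int(perm[i])) for i in range(n)]
        max_gap = int(rng.integers(3, 10))
        best_len, best_gap, best_sets = best_chain_oracle(points, max_gap)
        anchors = [mk_anchor(x, y) for x, y in points]
        blocks = chain_blocks(anchors, max_gap=max_gap, min_block=1)
        top = blocks[0]
        got = frozenset(points.index((a.rank1, a.rank2)) for a in top.anchors)
        assert top.score == best_len
        gap = sum(
            (b.rank1 - a.rank1 - 1) + (abs(b.rank2 - a.rank2) - 1)
            for a, b in zip(top.anchors, top.anchors[1:])
        )
        assert gap == best_gap
        assert got in best_sets

    def test_anchor_assigned_to_at_most_one_block(self):
        anchors = [mk_anchor(i, i) for i in range(10)]
        blocks = chain_blocks(anchors, min_block=2)
        seen = set()
        for b in blocks:
            for a in b.anchors:
                assert (a.rank1, a.rank2) not in seen
                seen.add((a.rank1, a.rank2))


class TestClassifyTandem:
    GENOME = toy_genome(
        [(f"g{i}", "chr1", 1 + 100 * i, 50 + 100 * i) for i in range(15)]
        + [(f"h{i}", "chr2", 1 + 100 * i, 50 + 100 * i) for i in range(15)]
    )

    def test_within_window_is_tandem(self):
        parts = classify_tandem([make_pair("g5", "g12", "paralog")], self.GENOME, window=10)
        assert len(parts["tandem"]) == 1  # rank distance 7

    def test_boundary_inclusive(self):
        parts = classify_tandem([make_pair("g0", "g10", "paralog")], self.GENOME, window=10)
        assert len(parts["tandem"]) == 1  # rank distance exactly 10

    def test_beyond_window_dispersed(self):
        parts = classify_tandem([make_pair("g0", "g11", "paralog")], self.GENOME, window=10)
        assert len(parts["dispersed"]) == 1

    def test_cross_chromosome_dispersed(self):
        parts = classify_tandem([make_pair("g0", "h0", "paralog")], self.GENOME, window=10)
        assert len(parts["dispersed"]) == 1

    def test_partition_total_and_disjoint(self, rng):
        ids = [f"g{i}" for i in range(15)] + [f"h{i}" for i in range(15)]
        pairs = []
        for _ in range(20):
            a, b = rng.choice(ids, 2, replace=False)
            pairs.append(make_pair(str(a), str(b), "paralog"))
        parts = classify_tandem(pairs, self.GENOME)
        assert len(parts["tandem"]) + len(parts["dispersed"]) == len(pairs)
        assert not ({p.key for p in parts["tandem"]} & {p.key for p in parts["dispersed"]})


class TestRestrictToBlocks:
    def _table(self, pairs):
        return pd.DataFrame({"a": [p.a for p in pairs], "b": [p.b for p in pairs]})

    def test_no_blocks_empty_subset(self):
        table = self._table([make_pair("a", "b", "paralog")])
        assert restrict_to_blocks(table, []).empty

    def test_all_anchored_identity(self):
        pairs = [make_pair(f"a{i}", f"b{i}", "paralog") for i in range(6)]
        anchors = [Anchor(p, "chr1", i, "chr2", i) for i, p in enumerate(pairs)]
        blocks = chain_blocks(anchors, min_block=5)
        table = self._table(pairs)
        out = restrict_to_blocks(table, blocks)
        assert len(out) == len(table)

    def test_subset_property(self, rng):
        pairs = [make_pair(f"a{i}", f"b{i}", "paralog") for i in range(20)]
        anchors = [Anchor(p, "chr1", i, "chr2", i) for i, p in enumerate(pairs[:8])]
        blocks = chain_blocks(anchors, min_block=5)
        table = self._table(pairs)
        out = restrict_to_blocks(table, blocks)
        merged = out.merge(table, on=["a", "b"])
        assert len(merged) == len(out) <= len(table)


class TestSyntenyDepth:
    GENOME = toy_genome([(f"g{i}", "chr1", 1 + 100 * i, 50 + 100 * i) for i in range(20)])

    def _block(self, bid, lo, hi):
        anchors = [
            Anchor(HomologPair(f"x{bid}{r}", f"y{bid}{r}"), "chrX", r, "chr1", r)
            for r in range(lo, hi + 1)
        ]
        return chain_blocks(anchors, min_block=2)[0]

    def test_single_block_coverage(self):
        depth, hist, modal = synteny_depth([self._block("a", 0, 9)], self.GENOME, axis=2)
        assert all(depth[f"g{i}"] == 1 for i in range(10))
        assert all(depth[f"g{i}"] == 0 for i in range(10, 20))
        assert modal == 1

    def test_stacked_blocks_depth_two(self):
        blocks = [self._block("a", 0, 9), self._block("b", 0, 9)]
        depth, hist, modal = synteny_depth(blocks, self.GENOME, axis=2)
        assert depth["g5"] == 2 and modal == 2 and hist[2] == 10


class TestColocalizationSpan:
    GENOME = toy_genome(
        [("a", "chrX", 100, 200), ("b", "chrX", 1100, 1200), ("c", "chrX", 500, 600),
         ("d", "chrX", 800, 850), ("e", "chrB", 10, 40)]
    )

    def test_span_arithmetic(self):
        (span,) = colocalization_span(["a", "b"], toy_genome([("a", "chrX", 100, 200), ("b", "chrX", 1100, 1200)]))
        assert span.span_bp == 1101 and span.n_genes == 2

    def test_single_gene_span_is_length(self):
        (span,) = colocalization_span(["e"], self.GENOME)
        assert span.span_bp == 31

    def test_primary_chromosome_flagged(self):
        spans = colocalization_span(["a", "b", "c", "d", "e"], self.GENOME)
        assert len(spans) == 2
        primary = [s for s in spans if s.primary]
        assert len(primary) == 1 and primary[0].chromosome == "chrX" and primary[0].n_genes == 4

    def test_unknown_gene_named_in_error(self):
        with pytest.raises(KeyError, match="ghost"):
            colocalization_span(["ghost"], self.GENOME)


class TestDotplot:
    def test_empty(self):
        assert dotplot_table([]).empty

    def test_single_anchor(self):
        df = dotplot_table([mk_anchor(3, 7)])
        assert df.iloc[0].tolist() == ["chr1", 3, "chr2", 7, "none"]

    def test_anchors_carry_block_ids(self):
        anchors = [mk_anchor(i, i) for i in range(6)]
        blocks = chain_blocks(anchors, min_block=5)
        df = dotplot_table(anchors, blocks)
        assert set(df["block_id"]) == {blocks[0].block_id}


class TestAnchorsFromPairs:
    def test_intragenome_suppresses_self_and_orders_axes(self):
        gm = toy_genome([("a", "chr1", 1, 9), ("b", "chr1", 100, 109), ("c", "chr2", 1, 9)])
        anchors = anchors_from_pairs(
            [make_pair("a", "b", "paralog"), make_pair("b", "c", "paralog"), HomologPair("a", "a")],
            gm,
            min_diagonal_distance=0,
        )
        assert len(anchors) == 2
        for a in anchors:
            assert (a.chrom1, a.rank1) <= (a.chrom2, a.rank2)

    def test_near_diagonal_tandem_anchors_excluded(self):
        gm = toy_genome([(f"g{i}", "chr1", 1 + 100 * i, 50 + 100 * i) for i in range(30)])
        pairs = [make_pair("g0", "g1", "paralog"), make_pair("g0", "g25", "paralog")]
        anchors = anchors_from_pairs(pairs, gm)
        assert [(a.rank1, a.rank2) for a in anchors] == [(0, 25)]


class TestRearrangementFragmentation:
    """More rearrangements chop planted WGD collinearity into shorter blocks."""

    @staticmethod
    def _mean_block_len(n_rearr):
        cfg = SimConfig(
            seed=77, n_genes=300, n_chromosomes=3, codons_per_gene=4,
            wgd_events=[(depth_to_mya(0.5), 1.0)],
            n_inversions=n_rearr, n_translocations=n_rearr,
        )
        genomes, _, truth = simulate(cfg)
        gm = genomes[0]
        pairs = [
            HomologPair(*sorted(k), kind="paralog") for k in truth.pairs_by_origin("wgd")
        ]
        anchors = anchors_from_pairs(pairs, gm)
        blocks = chain_blocks(anchors, max_gap=25, min_block=5)
        return blocks, np.mean([b.score for b in blocks]) if blocks else 0.0, truth

    def test_clean_wgd_full_coverage_then_degradation(self):
        blocks0, mean0, truth = self._mean_block_len(0)
        # every chromosome pair with planted duplicates yields a block
        chrom_pairs = {(b.chrom1, b.chrom2) for b in blocks0}
        assert len(chrom_pairs) >= 3
        anchored = set()
        for b in blocks0:
            anchored |= b.pair_keys()
        true_wgd = set(truth.pairs_by_origin("wgd"))
        assert len(anchored & true_wgd) / len(true_wgd) >= 0.8
        _, mean1, _ = self._mean_block_len(6)
        _, mean2, _ = self._mean_block_len(20)
        assert mean0 > mean1 > mean2
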