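import numpy as np
import pytest

from wgdscan import (
    HitTable,
    HomologyHit,
    block_significance,
    blocks_self,
    build_pairs,
    infer_blocks,
    rank_hits,
    score_pairs,
)
from wgdscan.colinearity import GenePair, null_chain_lengths

from conftest import make_annotation
from oracles import max_chain_oracle


def pairs_at(points):
    return [GenePair(f"a{x}", f"b{y}", x, y) for x, y in points]


def hit(q, s, score=100.0):
    return HomologyHit(q, s, score, 0.9, 1e-20, "other")


class TestBuildPairs:
    def test_groups_by_scaffold_pair(self):
        annot = make_annotation({"s1": 5, "s2": 5})
        hits = HitTable(hits=[hit("g0", "g5"), hit("g1", "g6"), hit("g2", "g7")])
        grouped = build_pairs(hits, annot, annot)
        assert set(grouped) == {("s1", "s2")}
        assert len(grouped[("s1", "s2")]) == 3

    def test_self_mode_drops_diagonal_hit(self):
        annot = make_annotation({"s1": 5})
        hits = HitTable(hits=[hit("g1", "g1")])
        assert build_pairs(hits, annot, annot, self_mode=True) == {}

    def test_self_mode_collapses_symmetric_hits(self):
        annot = make_annotation({"s1": 5})
        hits = HitTable(hits=[hit("g1", "g3"), hit("g3", "g1")])
        grouped = build_pairs(hits, annot, annot, self_mode=True)
        assert len(grouped[("s1", "s1")]) == 1
        p = grouped[("s1", "s1")][0]
        assert p.x <= p.y

    def test_unknown_gene_is_hard_error(self):
        annot = make_annotation({"s1": 2})
        with pytest.raises(KeyError):
            build_pairs(HitTable(hits=[hit("g0", "nope")]), annot, annot)


class TestInferBlocks:
    def test_gap_cap_excludes_distant_pair(self):
        blocks = infer_blocks(pairs_at([(1, 1), (2, 2), (3, 3), (10, 10)]),
                              max_gap=5, min_len=3)
        assert len(blocks) == 1
        assert blocks[0].length == 3
        assert {p.x for p in blocks[0].pairs} == {1, 2, 3}

    def test_perfect_antidiagonal(self):
        blocks = infer_blocks(pairs_at([(1, 5), (2, 4), (3, 3), (4, 2), (5, 1)]),
                              max_gap=50, min_len=4)
        assert len(blocks) == 1
        assert blocks[0].orientation == "antiparallel"
        assert blocks[0].length == 5

    def test_empty_input(self):
        assert infer_blocks([], max_gap=50, min_len=3) == []

    @pytest.mark.parametrize("trial", range(60))
    def test_first_chain_matches_exhaustive_oracle(self, trial):
        """DP extraction equals brute-force maximum chain on small instances."""
        rng = np.random.default_rng(5000 + trial)
        n = int(rng.integers(2, 13))
        max_gap = int(rng.choice([1, 2, 5, 50]))
        points = [(int(rng.integers(1, 15)), int(rng.integers(1, 15))) for _ in range(n)]
        points = list({p: None for p in points})  # dedupe, keep order
        blocks = infer_blocks(pairs_at(points), max_gap=max_gap, min_len=2)
        want = max_chain_oracle(points, max_gap)
        if want >= 2:
            assert blocks and blocks[0].length == want
        else:
            assert not blocks

    def test_blocks_are_pairwise_disjoint(self):
        rng = np.random.default_rng(77)
        points = list({(int(rng.integers(1, 40)), int(rng.integers(1, 40))): None
                       for _ in range(60)})
        blocks = infer_blocks(pairs_at(points), max_gap=10, min_len=3)
        seen = set()
        for b in blocks:
            for p in b.pairs:
                assert (p.x, p.y) not in seen
                seen.add((p.x, p.y))

    def test_deterministic(self):
        points = [(1, 3), (2, 1), (3, 4), (4, 2), (5, 5), (6, 6), (8, 7)]
        b1 = infer_blocks(pairs_at(points), max_gap=5, min_len=2)
        b2 = infer_blocks(pairs_at(points), max_gap=5, min_len=2)
        assert [(b.orientation, b.pairs) for b in b1] == [(b.orientation, b.pairs) for b in b2]


class TestBlockSignificance:
    def test_long_block_is_significant(self):
        block = infer_blocks(pairs_at([(i, i) for i in range(1, 11)]),
                             max_gap=5, min_len=5)[0]
        p = block_significance(block, 12, 500, 500, max_gap=5, n_perm=500, seed=1)
        assert p < 0.01

    def test_short_block_in_dense_scatter_is_not(self):
        rng = np.random.default_rng(3)
        points = list({(int(rng.integers(1, 21)), int(rng.integers(1, 21))): None
                       for _ in range(150)})
        blocks = infer_blocks(pairs_at(points), max_gap=50, min_len=2)
        # the densest scatter always chains; its length is typical of noise
        p = block_significance(blocks[0], len(points), 20, 20,
                               max_gap=50, n_perm=300, seed=2)
        assert p > 0.2

    def test_p_value_never_zero(self):
        block = infer_blocks(pairs_at([(i, i) for i in range(1, 30)]),
                             max_gap=2, min_len=5)[0]
        p = block_significance(block, 30, 1000, 1000, max_gap=2, n_perm=100, seed=0)
        assert 0 < p <= 1
        assert p >= 1 / 101


class TestOrchestration:
    def test_duplicated_scaffolds_give_full_span_blocks(self, tetraploid_lossfree):
        annot, store, truth = tetraploid_lossfree
        hits = rank_hits(score_pairs(store, store))
        blocks = blocks_self(annot, hits, max_gap=50, min_len=5, n_perm=200, seed=1)
        # every ancestral scaffold pairs with its duplicate in one long block
        spans = {}
        for b in blocks:
            key = (b.scaffold_a, b.scaffold_b)
            spans[key] = max(spans.get(key, 0), b.length)
        assert len(spans) >= annot.n_scaffolds // 2
        for (sa, sb), length in spans.items():
            assert length >= 0.9 * min(annot.scaffold_size(sa), annot.scaffold_size(sb))

    def test_min_len_monotonicity(self):
        rng = np.random.default_rng(8)
        points = list({(int(rng.integers(1, 60)), int(rng.integers(1, 60))): None
                       for _ in range(80)})
        b4 = infer_blocks(pairs_at(points), max_gap=10, min_len=4)
        b5 = infer_blocks(pairs_at(points), max_gap=10, min_len=5)
        lens4 = sorted(b.length for b in b4 if b.length >= 5)
        lens5 = sorted(b.length for b in b5)
        # every >=5 block still exists when the threshold tightens
        assert lens5 == lens4


class TestNullChainLengths:
    def test_reproducible_for_seed(self):
        a = null_chain_lengths(20, 100, 100, max_gap=10, n_perm=50, seed=5)
        b = null_chain_lengths(20, 100, 100, max_gap=10, n_perm=50, seed=5)
        assert np.array_equal(a, b)
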