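"""Alignment scoring, best-of-K selection, and database ranking."""

import numpy as np
import pytest

from ssealign.alignment_eval import (
    alignment_score,
    best_alignment,
    compare_structures,
    core_coverage,
    normalized_score,
    rank_database,
)
from ssealign.auxiliary_graph import build_auxiliary_graph
from ssealign.mis_enum import brute_force_top_k, enumerate_top_k
from ssealign.segment_scoring import (
    CandidatePair,
    ScoreMatrix,
    compute_score_matrix,
    top_r_candidates,
)
from ssealign import synthetic

from conftest import toy_spec


class TestAlignmentScore:
    MATRIX = ScoreMatrix({(0, 0): 8.3, (1, 1): 2.0, (2, 0): 1.5})

    def test_empty_is_zero(self):
        assert alignment_score([], self.MATRIX) == 0.0

    def test_single_pair(self):
        assert alignment_score([(0, 0)], self.MATRIX) == pytest.approx(8.3)

    def test_sum_of_three(self):
        got = alignment_score([(0, 0), (1, 1), (2, 0)], self.MATRIX)
        assert got == pytest.approx(8.3 + 2.0 + 1.5)

    def test_missing_entry_errors(self):
        with pytest.raises(KeyError):
            alignment_score([(9, 9)], self.MATRIX)


class TestNormalizedScore:
    def test_zero_score(self):
        assert normalized_score(0.0, 100, 50) == 0.0

    def test_arithmetic(self):
        assert normalized_score(10.0, 10, 10) == pytest.approx(0.1)

    def test_linearity(self):
        base = normalized_score(3.0, 17, 23)
        assert normalized_score(6.0, 17, 23) == pytest.approx(2 * base)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            normalized_score(1.0, 0, 10)


class TestCoreCoverage:
    def test_full_coverage_small_query(self):
        assert core_coverage(7, 7, 40) == pytest.approx(1.0)

    def test_full_coverage_small_target(self):
        assert core_coverage(4, 7, 4) == pytest.approx(1.0)

    def test_zero_matched(self):
        assert core_coverage(0, 5, 9) == 0.0

    def test_overflow_errors(self):
        with pytest.raises(ValueError):
            core_coverage(8, 7, 40)


class TestBestAlignment:
    def _setup(self):
        G = synthetic.random_mixed_graph(4, 0.3, seed=1)
        H = synthetic.random_mixed_graph(6, 0.3, seed=2)
        rng = np.random.default_rng(3)
        pairs = [CandidatePair(g, h, float(np.round(rng.random(), 3)))
                 for g in range(4) for h in range(6)
                 if G.sses[g].kind == H.sses[h].kind]
        matrix = ScoreMatrix({(p.g_index, p.h_index): p.score for p in pairs})
        X = build_auxiliary_graph(pairs, G, H, sequential=True)
        return G, H, X, matrix

    def test_k1_returns_maximum_set_alignment(self):
        G, H, X, matrix = self._setup()
        top1 = enumerate_top_k(X, 1)
        aln = best_alignment(top1, matrix, G, H)
        assert len(aln.matched_pairs) == top1[0].cardinality

    def test_raw_score_dominates_cardinality(self):
        # a size-4 set scoring 3.5 beats a size-5 set scoring 3.0
        from ssealign.mis_enum import RankedIndependentSet

        matrix = ScoreMatrix({(k, k): 0.875 for k in range(4)}
                             | {(k + 10, k): 0.6 for k in range(5)})
        G = synthetic.random_mixed_graph(15, 0.0, seed=5)
        H = synthetic.random_mixed_graph(15, 0.0, seed=6)
        big = RankedIndependentSet(frozenset(range(5)), 5, 3.0,
                                   tuple((k + 10, k) for k in range(5)))
        small = RankedIndependentSet(frozenset(range(5, 9)), 4, 3.5,
                                     tuple((k, k) for k in range(4)))
        aln = best_alignment([big, small], matrix, G, H)
        assert aln.S == pytest.approx(3.5)
        assert len(aln.matched_pairs) == 4

    def test_matches_exhaustive_scan(self):
        G, H, X, matrix = self._setup()
        topk = enumerate_top_k(X, 1000)
        aln = best_alignment(topk, matrix, G, H)
        oracle = max(
            alignment_score(list(s.pairs), matrix)
            for s in brute_force_top_k(X, 10 ** 6)
        )
        assert aln.S == pytest.approx(oracle)

    def test_pairs_injective_and_ordered(self):
        G, H, X, matrix = self._setup()
        aln = best_alignment(enumerate_top_k(X, 100), matrix, G, H)
        gs = [g for g, _ in aln.matched_pairs]
        hs = [h for _, h in aln.matched_pairs]
        assert len(set(gs)) == len(gs) and len(set(hs)) == len(hs)
        assert hs == sorted(hs)  # sequential mode: both strictly increasing


class TestComparePipeline:
    def test_self_comparison_identity(self, toy_proteins):
        for _, P in toy_proteins[:5]:
            aln = compare_structures(P, P, r=3, K=100)
            assert aln.matched_pairs == [(k, k) for k in range(P.graph.n_sses)]
            assert aln.core_cov == 1.0
            assert aln.Sn == pytest.approx(aln.S / P.graph.length ** 2)

    def test_orientation_preserved_when_swapped(self, toy_proteins):
        # B has fewer SSEs than A: pairs must still be (A index, B index)
        big = next(P for _, P in toy_proteins if P.graph.n_sses == 5)
        small = next(P for _, P in toy_proteins if P.graph.n_sses == 2)
        aln = compare_structures(big, small, r=3, K=100)
        for a, b in aln.matched_pairs:
            assert 0 <= a < big.graph.n_sses
            assert 0 <= b < small.graph.n_sses

    def test_planted_substructure_recovered(self):
        pair = synthetic.plant_common_structure(toy_spec(2), 3, seed=11)
        Q = pair.query.to_structure("q")
        T = pair.target.to_structure("t")
        aln = compare_structures(Q, T)
        assert aln.matched_pairs == sorted(pair.mapping.items())
        assert aln.core_cov == 1.0

    def test_monotone_in_k_and_r(self, toy_proteins):
        (_, A), (_, B) = toy_proteins[6], toy_proteins[9]
        s_by_k = [compare_structures(A, B, r=4, K=K).S for K in (1, 10, 100)]
        assert all(x <= y + 1e-12 for x, y in zip(s_by_k, s_by_k[1:]))
        s_by_r = [compare_structures(A, B, r=r, K=200).S for r in (1, 2, 4)]
        assert all(x <= y + 1e-12 for x, y in zip(s_by_r, s_by_r[1:]))

    def test_nonsequential_at_least_sequential_size(self, toy_proteins):
        (_, A), (_, B) = toy_proteins[3], toy_proteins[8]
        seq = compare_structures(A, B, r=4, K=500, sequential=True)
        nonseq = compare_structures(A, B, r=4, K=500, sequential=False)
        assert len(nonseq.matched_pairs) >= len(seq.matched_pairs)


class TestRankDatabase:
    def test_query_in_database_ranks_first(self, toy_proteins):
        db = toy_proteins[:8]
        for name, P in db[:3]:
            rows = rank_database(P, db, r=3, K=200)
            assert rows[0][0] == name

    def test_single_entry_trivially_first(self, toy_proteins):
        name, target = toy_proteins[4]
        rows = rank_database(toy_proteins[0][1], [(name, target)], r=3, K=100)
        assert rows[0][0] == name

    def test_planted_target_ranks_first(self):
        # database of full-size structures, each embedding one query's
        # elements: every query must retrieve its own host structure
        pairs = [
            synthetic.plant_common_structure(toy_spec(i), 3, seed=21 + i)
            for i in range(4)
        ]
        db = [(f"host{i}", p.target.to_structure(f"host{i}"))
              for i, p in enumerate(pairs)]
        for i, p in enumerate(pairs):
            rows = rank_database(p.query.to_structure("q"), db, r=4, K=300)
            assert rows[0][0] == f"host{i}"

    def test_empty_database_errors(self, toy_proteins):
        with pytest.raises(ValueError):
            rank_database(toy_proteins[0][1], [])
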