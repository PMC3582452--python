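"""Width-2 embedding by 2-SAT, validated against exhaustive oracles."""

import itertools

import numpy as np
import pytest

from ssealign.reductions import bare_graph
from ssealign.two_sat import (
    EmbeddingInstance,
    TwoCnfFormula,
    build_formula,
    embed_width2,
    solve_2sat,
    verify_embedding,
)


def random_width2_instance(seed):
    rng = np.random.default_rng(seed)
    nG = int(rng.integers(1, 7))
    nH = int(rng.integers(max(nG, 2), nG + 4))
    G = bare_graph(nG, {(i, j) for i in range(nG) for j in range(i + 1, nG)
                        if rng.random() < 0.4})
    H = bare_graph(nH, {(i, j) for i in range(nH) for j in range(i + 1, nH)
                        if rng.random() < 0.5})
    lists = {
        v: tuple(sorted(rng.choice(nH, size=int(rng.integers(1, 3)),
                                   replace=False).tolist()))
        for v in range(nG)
    }
    return EmbeddingInstance(G=G, H=H, lists=lists)


def brute_force_decide(inst):
    """Try every combination of list choices."""
    n = inst.G.n_sses
    return any(
        verify_embedding(inst.G, inst.H, dict(enumerate(choice)),
                         lists=inst.lists)
        for choice in itertools.product(*[inst.lists[v] for v in range(n)])
    )


class TestBuildFormula:
    def test_single_vertex_unit_clause(self):
        inst = EmbeddingInstance(G=bare_graph(1, set()), H=bare_graph(1, set()),
                                 lists={0: (0,)})
        f = build_formula(inst)
        assert f.n_variables == 1
        assert f.clauses == [(1,)]

    def test_both_vertices_forced_to_same_host_unsat(self):
        inst = EmbeddingInstance(G=bare_graph(2, set()), H=bare_graph(2, set()),
                                 lists={0: (0,), 1: (0,)})
        assert solve_2sat(build_formula(inst)) is None

    def test_clause_families_hand_enumerated(self):
        # G: 2-path with interaction edge; H: 2-path with none;
        # both lists {0, 1}; variables (0,0)=1 (0,1)=2 (1,0)=3 (1,1)=4
        inst = EmbeddingInstance(
            G=bare_graph(2, {(0, 1)}), H=bare_graph(2, set()),
            lists={0: (0, 1), 1: (0, 1)},
        )
        f = build_formula(inst)
        expected = {
            # (a) well-definedness
            frozenset({1, 2}), frozenset({-1, -2}),
            frozenset({3, 4}), frozenset({-3, -4}),
            # (b) injectivity + order: forbid u' <= v'
            frozenset({-1, -3}), frozenset({-2, -3}), frozenset({-2, -4}),
            # (c) edge preservation: H has no edges, forbid everything
            frozenset({-1, -4}),
        }
        assert {frozenset(c) for c in f.clauses} == expected

    def test_width_three_rejected(self):
        inst = EmbeddingInstance(G=bare_graph(1, set()), H=bare_graph(3, set()),
                                 lists={0: (0, 1, 2)})
        with pytest.raises(ValueError, match="width"):
            build_formula(inst)

    def test_empty_list_rejected(self):
        inst = EmbeddingInstance(G=bare_graph(1, set()), H=bare_graph(1, set()),
                                 lists={0: ()})
        with pytest.raises(ValueError, match="empty"):
            build_formula(inst)

    def test_dimacs_dump(self):
        inst = EmbeddingInstance(G=bare_graph(1, set()), H=bare_graph(2, set()),
                                 lists={0: (0, 1)})
        text = build_formula(inst).to_dimacs()
        assert text.startswith("p cnf 2 2\n")
        assert "1 2 0" in text


class TestSolve2Sat:
    def test_unit_clause(self):
        f = TwoCnfFormula(var_of={(0, 0): 1}, clauses=[(1,)])
        assert solve_2sat(f) == {1: True}

    def test_contradiction(self):
        f = TwoCnfFormula(var_of={(0, 0): 1}, clauses=[(1,), (-1,)])
        assert solve_2sat(f) is None

    def test_agrees_with_truth_table_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            m = int(rng.integers(1, 9))
            n_clauses = int(rng.integers(1, 3 * m + 1))
            clauses = []
            for _ in range(n_clauses):
                width = min(int(rng.integers(1, 3)), m)
                lits = rng.choice(np.arange(1, m + 1), size=width,
                                  replace=False)
                clauses.append(tuple(int(l) * (1 if rng.random() < 0.5 else -1)
                                     for l in lits))
            f = TwoCnfFormula(var_of={(0, k): k + 1 for k in range(m)},
                              clauses=clauses)
            got = solve_2sat(f)
            sat = any(
                all(any(((assign >> (abs(l) - 1)) & 1) == int(l > 0) for l in c)
                    for c in clauses)
                for assign in range(1 << m)
            )
            assert (got is not None) == sat
            if got is not None:
                for c in clauses:
                    assert any(got[abs(l)] == (l > 0) for l in c)


class TestEmbedWidth2:
    def test_identity_embedding(self):
        G = bare_graph(2, {(0, 1)})
        H = bare_graph(2, {(0, 1)})
        inst = EmbeddingInstance(G=G, H=H, lists={0: (0,), 1: (1,)})
        assert embed_width2(inst) == {0: 0, 1: 1}

    def test_missing_host_edge_gives_none(self):
        G = bare_graph(2, {(0, 1)})
        H = bare_graph(2, set())
        inst = EmbeddingInstance(G=G, H=H, lists={0: (0,), 1: (1,)})
        assert embed_width2(inst) is None

    def test_empty_list_rejects_instance(self):
        inst = EmbeddingInstance(G=bare_graph(1, set()), H=bare_graph(1, set()),
                                 lists={0: ()})
        assert embed_width2(inst) is None

    def test_decision_matches_brute_force(self):
        for seed in range(60):
            inst = random_width2_instance(seed)
            f = embed_width2(inst)
            assert (f is not None) == brute_force_decide(inst)
            if f is not None:
                assert verify_embedding(inst.G, inst.H, f, lists=inst.lists)


class TestVerifyEmbedding:
    def test_identity_map_valid(self):
        G = bare_graph(3, {(0, 2)})
        assert verify_embedding(G, G, {0: 0, 1: 1, 2: 2})

    def test_order_reversal_invalid(self):
        G = bare_graph(2, set())
        assert not verify_embedding(G, G, {0: 1, 1: 0})

    def test_non_injective_invalid(self):
        G = bare_graph(2, set())
        H = bare_graph(2, set())
        assert not verify_embedding(G, H, {0: 0, 1: 0})

    def test_list_membership_checked(self):
        G = bare_graph(1, set())
        H = bare_graph(2, set())
        assert not verify_embedding(G, H, {0: 1}, lists={0: (0,)})

    def test_matches_condition_by_condition_reimplementation(self):
        rng = np.random.default_rng(17)
        for seed in range(40):
            inst = random_width2_instance(seed)
            nG, nH = inst.G.n_sses, inst.H.n_sses
            size = int(rng.integers(0, nG + 1))
            vs = rng.choice(nG, size=size, replace=False)
            f = {int(v): int(rng.integers(0, nH)) for v in vs}
            direct = (
                len(set(f.values())) == len(f)
                and all((v < u) == (f[v] < f[u])
                        for v in f for u in f if v != u)
                and all(inst.H.has_edge(f[v], f[u])
                        for v, u in inst.G.interaction_edges
                        if v in f and u in f)
            )
            assert verify_embedding(inst.G, inst.H, f) == direct
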