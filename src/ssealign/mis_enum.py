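"""Top-K maximum independent set enumeration.

Alignments correspond to independent sets of the auxiliary conflict
graph, so the K best candidate alignments are the K best maximal
independent sets under the total order

    (cardinality descending, total score descending,
     lexicographic vertex-id tuple ascending).

Maximal independent sets are enumerated as maximal cliques of the
complement graph by a branch-and-bound recursion (pivoted
Bron-Kerbosch-style branching over integer bitsets).  Once K sets are in
hand, any branch whose optimistic size bound |R| + |P| falls below the
current K-th best cardinality is pruned, which keeps enumeration fast
when only the near-optimal sets are wanted.  A guarded exhaustive
subset-scan oracle is provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

from ssealign.auxiliary_graph import AuxiliaryGraph

BRUTE_FORCE_LIMIT = 20


@dataclass(frozen=True)
class RankedIndependentSet:
    """One enumerated alignment candidate.

    ``members`` are auxiliary-graph vertex ids; ``pairs`` the corresponding
    (g_index, h_index) mappings; ``total_score`` the sum of member
    candidate-pair scores.
    """

    members: frozenset[int]
    cardinality: int
    total_score: float
    pairs: tuple[tuple[int, int], ...]

    def sort_key(self) -> tuple:
        return (-self.cardinality, -self.total_score, tuple(sorted(self.members)))


def _ranked(mask: int, X: AuxiliaryGraph) -> RankedIndependentSet:
    members = sorted(_bits(mask))
    # summed in sorted member order so equal sets always yield identical floats
    score = sum(X.vertices[k].score for k in members)
    pairs = tuple((X.vertices[k].g_index, X.vertices[k].h_index) for k in members)
    return RankedIndependentSet(
        members=frozenset(members),
        cardinality=len(members),
        total_score=float(score),
        pairs=pairs,
    )


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def enumerate_top_k(X: AuxiliaryGraph, K: int) -> list[RankedIndependentSet]:
    """The K best maximal independent sets of X, best first.

    The first element is always a maximum independent set.  Fewer than K
    sets are returned when the graph has fewer maximal independent sets.
    An empty graph yields the single empty set.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = X.n_vertices
    if n == 0:
        return [_ranked(0, X)]
    adj = X.adjacency_bitsets()
    full = (1 << n) - 1
    # complement adjacency: maximal independent sets of X are maximal
    # cliques of the complement
    cadj = [full & ~adj[v] & ~(1 << v) for v in range(n)]

    found: list[RankedIndependentSet] = []
    state = {"threshold": 0, "have_k": False}

    def flush() -> None:
        found.sort(key=RankedIndependentSet.sort_key)
        del found[K:]
        if len(found) == K:
            state["threshold"] = found[-1].cardinality
            state["have_k"] = True

    def expand(r_mask: int, r_size: int, P: int, Xs: int) -> None:
        if P == 0 and Xs == 0:
            found.append(_ranked(r_mask, X))
            if len(found) >= 4 * K + 64:
                flush()
            return
        if state["have_k"] and r_size + P.bit_count() < state["threshold"]:
            return
        # pivot: vertex of P|Xs covering the most of P (lowest id on ties)
        pivot, best_cov = -1, -1
        for u in _bits(P | Xs):
            cov = (P & cadj[u]).bit_count()
            if cov > best_cov:
                pivot, best_cov = u, cov
        ext = P & ~cadj[pivot]
        for v in _bits(ext):
            bv = 1 << v
            expand(r_mask | bv, r_size + 1, P & cadj[v], Xs & cadj[v])
            P &= ~bv
            Xs |= bv

    expand(0, 0, full, 0)
    flush()
    return found


def brute_force_top_k(X: AuxiliaryGraph, K: int) -> list[RankedIndependentSet]:
    """Exhaustive oracle: subset-scan enumeration of maximal independent sets.

    Guarded to graphs of at most 20 vertices; the guard is a hard error,
    never silent truncation.
    """
    n = X.n_vertices
    if n > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute force limited to {BRUTE_FORCE_LIMIT} vertices, got {n}"
        )
    if K < 1:
        raise ValueError("K must be >= 1")
    if n == 0:
        return [_ranked(0, X)]
    adj = X.adjacency_bitsets()
    indep = bytearray(1 << n)
    indep[0] = 1
    results = []
    for mask in range(1, 1 << n):
        low = mask & -mask
        v = low.bit_length() - 1
        rest = mask ^ low
        if indep[rest] and (adj[v] & rest) == 0:
            indep[mask] = 1
            if all((mask >> u) & 1 or (adj[u] & mask) for u in range(n)):
                results.append(_ranked(mask, X))
    results.sort(key=RankedIndependentSet.sort_key)
    return results[:K]


def maximum_independent_set(X: AuxiliaryGraph) -> RankedIndependentSet:
    """A maximum independent set of X (the top-1 enumeration result)."""
    return enumerate_top_k(X, 1)[0]
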