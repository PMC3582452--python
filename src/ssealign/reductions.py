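"""Ground-truthed hard instances for validating the embedding machinery.

The partial-embedding problem is NP-complete already at map width 1, via
a reduction from CLIQUE: both graphs copy the clique instance's vertex
set on a path, the query's interaction edges form a complete graph, the
host keeps the original edges, and every list is the single same-index
vertex.  A subset of query vertices then embeds validly iff it induces a
clique in the original graph, so brute-force clique search provides an
exact oracle for the whole alignment pipeline.
"""

from __future__ import annotations

import networkx as nx

from ssealign.structure_graph import HELIX, SSE, MixedStructureGraph
from ssealign.two_sat import EmbeddingInstance

BRUTE_FORCE_VERTEX_LIMIT = 12


def bare_graph(
    n: int,
    edges: set[tuple[int, int]],
    protein_id: str = "graph",
    kinds: list[str] | None = None,
) -> MixedStructureGraph:
    """A coordinate-free mixed graph with n vertices and the given edges.

    SSE spans are fabricated (3 residues each, consecutive) purely to
    satisfy the container invariants.
    """
    kinds = kinds or [HELIX] * n
    sses = [
        SSE(index=i, kind=kinds[i], start_res=3 * i + 1, end_res=3 * i + 3)
        for i in range(n)
    ]
    return MixedStructureGraph(
        protein_id=protein_id,
        sses=sses,
        interaction_edges=set(edges),
        length=max(3 * n, 1),
    )


def clique_to_embedding(Gp: nx.Graph, k: int) -> tuple[EmbeddingInstance, int]:
    """Encode a CLIQUE instance (Gp, k) as a width-1 embedding instance.

    The query G carries a complete interaction-edge set over n vertices,
    the host H carries Gp's edges, and L(v_i) = {u_i}.  Gp has a k-clique
    iff the instance admits a valid partial embedding of size >= k.
    """
    nodes = sorted(Gp.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    G = bare_graph(
        n,
        {(i, j) for i in range(n) for j in range(i + 1, n)},
        protein_id="clique-query",
    )
    H = bare_graph(
        n,
        {(min(index[a], index[b]), max(index[a], index[b])) for a, b in Gp.edges()},
        protein_id="clique-host",
    )
    lists = {i: (i,) for i in range(n)}
    return EmbeddingInstance(G=G, H=H, lists=lists), k


def max_embedding_bruteforce(
    inst: EmbeddingInstance, sequential: bool = True
) -> tuple[int, dict[int, int]]:
    """Largest valid partial embedding by exhaustive search (guarded).

    Explores every subset of query vertices and every choice of images
    from the lists, pruning only extensions that already violate the
    (hereditary) validity conditions.  ``sequential=False`` drops the
    chain-order condition, matching the non-sequential alignment mode.
    Hard error above the vertex limit, never silent truncation.
    """
    n = inst.G.n_sses
    if n > BRUTE_FORCE_VERTEX_LIMIT:
        raise ValueError(
            f"exhaustive search limited to {BRUTE_FORCE_VERTEX_LIMIT} "
            f"query vertices, got {n}"
        )
    best_size = 0
    best_map: dict[int, int] = {}

    def extend(v: int, chosen: list[tuple[int, int]]) -> None:
        nonlocal best_size, best_map
        if len(chosen) > best_size:
            best_size = len(chosen)
            best_map = dict(chosen)
        if v == n:
            return
        # option 1: leave v unmapped
        extend(v + 1, chosen)
        # option 2: map v to each feasible image
        for h in inst.lists.get(v, ()):
            ok = True
            for (u, hu) in chosen:  # all u < v
                if hu == h:
                    ok = False
                elif sequential and not hu < h:
                    ok = False
                elif inst.G.has_edge(u, v) and not inst.H.has_edge(hu, h):
                    ok = False
                if not ok:
                    break
            if ok:
                extend(v + 1, chosen + [(v, h)])

    extend(0, [])
    return best_size, best_map


def max_clique_bruteforce(Gp: nx.Graph) -> int:
    """Maximum clique size by exhaustive extension (small graphs only)."""
    nodes = sorted(Gp.nodes())
    if len(nodes) > BRUTE_FORCE_VERTEX_LIMIT:
        raise ValueError("clique brute force limited to small graphs")
    best = 0

    def extend(cand: list, clique: list) -> None:
        nonlocal best
        best = max(best, len(clique))
        for i, v in enumerate(cand):
            if all(Gp.has_edge(v, u) for u in clique):
                extend(cand[i + 1:], clique + [v])

    extend(nodes, [])
    return best
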