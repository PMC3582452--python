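"""The auxiliary conflict graph.

Each candidate mapping g_i -> h_j becomes a vertex x_ij.  Two vertices
x_ij and x_kl conflict (are joined by an edge) iff

  1. i = k or j = l                      (the map would not be injective);
  2. (i < k and j > l) or (i > k and j < l)
                                         (the mapping would cross chain
                                          order; applied only in
                                          sequential mode); or
  3. {g_i, g_k} is an interaction edge of G but {h_j, h_l} is not one of H
                                         (a contact of G would be lost).

Independent sets of this graph are exactly the valid partial alignments,
so maximum common subgraph search reduces to maximum independent set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ssealign.segment_scoring import CandidatePair
from ssealign.structure_graph import MixedStructureGraph

logger = logging.getLogger(__name__)


@dataclass
class AuxiliaryGraph:
    """Conflict graph over candidate SSE mappings.

    Vertices are indexed 0..n-1 in the order of ``vertices``; edges are
    stored as sorted index pairs.  ``sequential`` records whether the
    crossing condition was applied when the edges were built.
    """

    vertices: list[CandidatePair]
    edges: set[tuple[int, int]]
    sequential: bool = True

    def __post_init__(self) -> None:
        n = len(self.vertices)
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loop in auxiliary graph")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError("edge endpoint outside vertex range")
            canon.add((min(a, b), max(a, b)))
        self.edges = canon

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def adjacency_bitsets(self) -> list[int]:
        """Neighbourhoods as integer bitsets (vertex k -> bit k)."""
        adj = [0] * len(self.vertices)
        for a, b in self.edges:
            adj[a] |= 1 << b
            adj[b] |= 1 << a
        return adj

    def to_edge_list(self) -> str:
        """Plain edge-list dump: one header line per vertex, then edges."""
        out = [f"v {k} {p.g_index} {p.h_index} {p.score:.6f}"
               for k, p in enumerate(self.vertices)]
        out.extend(f"e {a} {b}" for a, b in sorted(self.edges))
        return "\n".join(out) + "\n"


def _conflicts(
    p: CandidatePair,
    q: CandidatePair,
    G: MixedStructureGraph,
    H: MixedStructureGraph,
    sequential: bool,
) -> bool:
    i, j = p.g_index, p.h_index
    k, l = q.g_index, q.h_index
    if i == k or j == l:
        return True
    if sequential and ((i < k and j > l) or (i > k and j < l)):
        return True
    if G.has_edge(i, k) and not H.has_edge(j, l):
        return True
    return False


def build_auxiliary_graph(
    pairs: list[CandidatePair],
    G: MixedStructureGraph,
    H: MixedStructureGraph,
    sequential: bool = True,
) -> AuxiliaryGraph:
    """Construct the conflict graph over the given candidate pairs.

    Duplicate (g, h) pairs are deduplicated keeping the maximum score.
    Vertices are ordered by (g_index, h_index) for reproducibility.
    """
    best: dict[tuple[int, int], CandidatePair] = {}
    for p in pairs:
        if not (0 <= p.g_index < G.n_sses and 0 <= p.h_index < H.n_sses):
            raise ValueError(f"candidate pair {p} outside graph ranges")
        key = (p.g_index, p.h_index)
        if key not in best or p.score > best[key].score:
            best[key] = p
    vertices = [best[k] for k in sorted(best)]
    edges = {
        (a, b)
        for a in range(len(vertices))
        for b in range(a + 1, len(vertices))
        if _conflicts(vertices[a], vertices[b], G, H, sequential)
    }
    return AuxiliaryGraph(vertices=vertices, edges=edges, sequential=sequential)


def verify_alignment(
    pairs_subset: list[CandidatePair] | list[tuple[int, int]],
    G: MixedStructureGraph,
    H: MixedStructureGraph,
    sequential: bool = True,
) -> bool:
    """Check a set of pairs directly against the embedding conditions.

    True iff the subset is an injective partial map that preserves chain
    order (in sequential mode) and maps every interaction edge of G inside
    the subset onto an interaction edge of H.  This is computed from G and
    H alone, independently of the auxiliary graph, and serves as its
    cross-oracle: a subset passes iff it is independent in the conflict
    graph.
    """
    mapped = []
    for p in pairs_subset:
        if isinstance(p, CandidatePair):
            mapped.append((p.g_index, p.h_index))
        else:
            mapped.append((int(p[0]), int(p[1])))
    gs = [g for g, _ in mapped]
    hs = [h for _, h in mapped]
    if len(set(gs)) != len(gs) or len(set(hs)) != len(hs):
        return False
    for a in range(len(mapped)):
        i, j = mapped[a]
        for b in range(a + 1, len(mapped)):
            k, l = mapped[b]
            if sequential and (i < k) != (j < l):
                return False
            if G.has_edge(i, k) and not H.has_edge(j, l):
                return False
    return True


def trim_auxiliary_graph(
    X: AuxiliaryGraph,
    min_score: float | None = None,
    keep_fraction: float | None = None,
) -> AuxiliaryGraph:
    """Drop low-scoring candidate vertices and return the induced subgraph.

    ``min_score`` removes every vertex whose pair score is below the
    threshold; ``keep_fraction`` instead keeps the top fraction of
    candidates per query SSE (at least one).  With neither given the graph
    is returned unchanged — trimming is an explicit opt-in filter, not a
    hidden heuristic.
    """
    if min_score is None and keep_fraction is None:
        return X
    keep: list[int] = []
    if min_score is not None:
        keep = [k for k, p in enumerate(X.vertices) if p.score >= min_score]
    else:
        if not (0 < keep_fraction <= 1):
            raise ValueError("keep_fraction must be in (0, 1]")
        by_g: dict[int, list[int]] = {}
        for k, p in enumerate(X.vertices):
            by_g.setdefault(p.g_index, []).append(k)
        for g, idxs in sorted(by_g.items()):
            idxs.sort(key=lambda k: (-X.vertices[k].score, X.vertices[k].h_index))
            n_keep = max(1, round(len(idxs) * keep_fraction))
            keep.extend(idxs[:n_keep])
        keep.sort()
    old_to_new = {old: new for new, old in enumerate(keep)}
    vertices = [X.vertices[k] for k in keep]
    edges = {
        (old_to_new[a], old_to_new[b])
        for a, b in X.edges
        if a in old_to_new and b in old_to_new
    }
    logger.info("trimmed auxiliary graph: %d -> %d vertices",
                X.n_vertices, len(vertices))
    return AuxiliaryGraph(vertices=vertices, edges=edges,
                          sequential=X.sequential)
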