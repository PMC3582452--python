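"""Exact polynomial-time embedding for map width 2 via 2-SAT.

The list-embedding problem asks for an injection f from the query graph G
into the host H with f(v) drawn from a per-vertex list L(v), preserving
the chain order defined by the spanning arc paths and mapping every
interaction edge of G onto one of H.  When every list has at most two
entries the problem reduces to 2-CNF satisfiability: one Boolean variable
per (vertex, allowed image) pair, with three clause families enforcing
well-definedness, injectivity plus order, and edge preservation.  The
formula is solved by the standard implication-graph / strongly-connected-
components test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ssealign.structure_graph import MixedStructureGraph


@dataclass
class EmbeddingInstance:
    """A list-embedding instance (G, H, L).

    ``lists`` maps each G-vertex index to the tuple of H-vertex indices it
    may be mapped to.  The *map width* is the largest list size.
    """

    G: MixedStructureGraph
    H: MixedStructureGraph
    lists: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        for v, lst in self.lists.items():
            if not (0 <= v < self.G.n_sses):
                raise ValueError(f"list for unknown G-vertex {v}")
            for h in lst:
                if not (0 <= h < self.H.n_sses):
                    raise ValueError(f"list of {v} references unknown H-vertex {h}")

    @property
    def map_width(self) -> int:
        return max((len(lst) for lst in self.lists.values()), default=0)


@dataclass
class TwoCnfFormula:
    """A 2-CNF formula over (G-vertex, image) variables.

    Variables are numbered 1..m; a literal is a signed variable id.
    ``var_of`` maps the (v, h) pair to its variable id.
    """

    var_of: dict[tuple[int, int], int]
    clauses: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return len(self.var_of)

    def to_dimacs(self) -> str:
        out = [f"p cnf {self.n_variables} {len(self.clauses)}"]
        for clause in self.clauses:
            out.append(" ".join(str(l) for l in clause) + " 0")
        return "\n".join(out) + "\n"


def build_formula(inst: EmbeddingInstance) -> TwoCnfFormula:
    """Translate a width-2 instance into the three clause families.

    (a) per vertex, the image is chosen and unique; (b) for every ordered
    vertex pair of G, images that would collide or violate chain order
    are mutually excluded; (c) for every interaction edge of G, image
    pairs not joined in H are mutually excluded.  An empty list rejects
    the instance; width above 2 needs the general (independent-set)
    route.
    """
    nG = inst.G.n_sses
    for v in range(nG):
        lst = inst.lists.get(v, ())
        if len(lst) == 0:
            raise ValueError(f"vertex {v} has an empty list; instance rejected")
        if len(lst) > 2:
            raise ValueError(
                f"vertex {v} has {len(lst)} allowed images; map width must be <= 2"
            )

    var_of: dict[tuple[int, int], int] = {}
    for v in range(nG):
        for h in inst.lists[v]:
            if (v, h) not in var_of:
                var_of[(v, h)] = len(var_of) + 1
    clauses: list[tuple[int, ...]] = []

    # (a) well-definedness: exactly one image per vertex
    for v in range(nG):
        lst = tuple(dict.fromkeys(inst.lists[v]))
        if len(lst) == 1:
            clauses.append((var_of[(v, lst[0])],))
        else:
            x1, x2 = var_of[(v, lst[0])], var_of[(v, lst[1])]
            clauses.append((x1, x2))
            clauses.append((-x1, -x2))

    # (b) injectivity and order: v before u in G's path forbids images
    # with u's image at or before v's image in H's path
    for v in range(nG):
        for u in range(v + 1, nG):
            for vp in inst.lists[v]:
                for up in inst.lists[u]:
                    if up <= vp:
                        clauses.append((-var_of[(v, vp)], -var_of[(u, up)]))

    # (c) edge preservation: a G-edge may not land on a non-edge of H
    for v, u in sorted(inst.G.interaction_edges):
        for vp in inst.lists[v]:
            for up in inst.lists[u]:
                if not inst.H.has_edge(vp, up) or vp == up:
                    clauses.append((-var_of[(v, vp)], -var_of[(u, up)]))

    return TwoCnfFormula(var_of=var_of, clauses=clauses)


def solve_2sat(f: TwoCnfFormula) -> dict[int, bool] | None:
    """Satisfy a 2-CNF formula or report UNSAT (None).

    Implication graph over 2m literal nodes; the formula is satisfiable
    iff no variable shares a strongly connected component with its
    negation.  Assignments follow the reverse topological rule (a literal
    is true when its component comes after its negation's), so the result
    is deterministic.
    """
    m = f.n_variables

    def node(lit: int) -> int:
        v = abs(lit) - 1
        return 2 * v + (0 if lit > 0 else 1)

    imp = nx.DiGraph()
    imp.add_nodes_from(range(2 * m))
    for clause in f.clauses:
        if len(clause) == 1:
            (a,) = clause
            imp.add_edge(node(-a), node(a))
        elif len(clause) == 2:
            a, b = clause
            imp.add_edge(node(-a), node(b))
            imp.add_edge(node(-b), node(a))
        else:
            raise ValueError("clause with more than two literals")

    cond = nx.condensation(imp)
    comp_of = cond.graph["mapping"]
    order = {c: i for i, c in enumerate(nx.topological_sort(cond))}
    assignment: dict[int, bool] = {}
    for var in range(1, m + 1):
        pos, neg = comp_of[node(var)], comp_of[node(-var)]
        if pos == neg:
            return None
        assignment[var] = order[pos] > order[neg]
    return assignment


def embed_width2(inst: EmbeddingInstance) -> dict[int, int] | None:
    """Solve a width-2 instance exactly; None when no valid embedding exists.

    Decodes the satisfying assignment into the vertex map and checks it
    against :func:`verify_embedding` before returning.
    """
    try:
        formula = build_formula(inst)
    except ValueError as exc:
        if "empty list" in str(exc):
            return None
        raise
    assignment = solve_2sat(formula)
    if assignment is None:
        return None
    f: dict[int, int] = {}
    for (v, h), var in formula.var_of.items():
        if assignment[var]:
            if v in f:
                raise AssertionError("two images assigned to one vertex")
            f[v] = h
    if not verify_embedding(inst.G, inst.H, f, lists=inst.lists):
        raise AssertionError("2-SAT decoding produced an invalid embedding")
    return f


def verify_embedding(
    G: MixedStructureGraph,
    H: MixedStructureGraph,
    f: dict[int, int],
    lists: dict[int, tuple[int, ...]] | None = None,
    mode: str = "iff",
) -> bool:
    """Check a (partial) vertex map against the embedding conditions.

    Conditions: the map is injective; each image lies in the vertex's
    list (when lists are given); chain order is preserved; every
    interaction edge of G between mapped vertices lands on one of H.
    ``mode`` selects the order condition: "iff" requires order agreement
    in both directions (whole-graph embedding), "forward" only that G's
    order implies H's (the partial-embedding variant).  Since arc sets
    are spanning paths, order reduces to index comparison and the two
    modes coincide for injective maps; both are kept to mirror the two
    problem definitions.
    """
    if mode not in ("iff", "forward"):
        raise ValueError(f"unknown mode {mode!r}")
    images = list(f.values())
    if len(set(images)) != len(images):
        return False
    for v, h in f.items():
        if not (0 <= v < G.n_sses and 0 <= h < H.n_sses):
            return False
        if lists is not None and h not in lists.get(v, ()):
            return False
    keys = sorted(f)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            v, u = keys[a], keys[b]
            # v < u means a directed path v -> u along G's arc path
            if not f[v] < f[u]:
                return False
            if mode == "iff" and (f[v] < f[u]) != (v < u):
                return False
    for v, u in G.interaction_edges:
        if v in f and u in f and not H.has_edge(f[v], f[u]):
            return False
    return True
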