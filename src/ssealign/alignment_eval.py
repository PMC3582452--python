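"""Alignment scoring, selection, and database ranking.

An enumerated independent set becomes an alignment by summing its SSE
pair scores: S is the raw sum, Sn = S / (l_A * l_B) normalizes by the two
chain lengths (used for cross-protein ranking), and CORE-COV is the
number of matched SSEs over the smaller structure's SSE count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

from ssealign.auxiliary_graph import build_auxiliary_graph, trim_auxiliary_graph
from ssealign.mis_enum import RankedIndependentSet, enumerate_top_k
from ssealign.segment_scoring import (
    ScoreMatrix,
    compute_score_matrix,
    top_r_candidates,
)
from ssealign.structure_graph import ProteinStructure

logger = logging.getLogger(__name__)

DEFAULT_R = 5
DEFAULT_K = 1000


@dataclass
class Alignment:
    """A scored SSE correspondence between two structures.

    ``matched_pairs`` holds (index in A, index in B) tuples sorted by the
    first coordinate, injective in both coordinates; in sequential mode
    both coordinate sequences are strictly increasing.
    """

    matched_pairs: list[tuple[int, int]]
    S: float
    Sn: float
    core_cov: float
    sequential: bool
    a_id: str = "A"
    b_id: str = "B"
    pair_scores: list[float] | None = None  # aligned with matched_pairs

    def to_json(self) -> str:
        return json.dumps(
            {
                "a_id": self.a_id,
                "b_id": self.b_id,
                "matched_pairs": self.matched_pairs,
                "S": self.S,
                "Sn": self.Sn,
                "core_cov": self.core_cov,
                "sequential": self.sequential,
            },
            indent=2,
        )

    def to_tsv(self, A: ProteinStructure | None = None,
               B: ProteinStructure | None = None) -> str:
        rows = ["a_index\tb_index\ta_span\tb_span\tpair_score"]
        for k, (a, b) in enumerate(self.matched_pairs):
            a_span = b_span = "-"
            score = (f"{self.pair_scores[k]:.4f}"
                     if self.pair_scores is not None else "-")
            if A is not None:
                s = A.graph.sses[a]
                a_span = f"{s.start_res}-{s.end_res}"
            if B is not None:
                s = B.graph.sses[b]
                b_span = f"{s.start_res}-{s.end_res}"
            rows.append(f"{a}\t{b}\t{a_span}\t{b_span}\t{score}")
        rows.append(f"# S={self.S:.4f} Sn={self.Sn:.6g} "
                    f"CORE-COV={round(self.core_cov * 100)}%")
        return "\n".join(rows) + "\n"


def alignment_score(
    pairs: list[tuple[int, int]], score_matrix: ScoreMatrix
) -> float:
    """Raw alignment score S: the sum of the matched SSE pair scores."""
    total = 0.0
    for key in pairs:
        key = (int(key[0]), int(key[1]))
        if key not in score_matrix:
            raise KeyError(f"pair {key} missing from score matrix")
        total += score_matrix[key]
    return total


def normalized_score(S: float, lA: int, lB: int) -> float:
    """Length-normalized score Sn = S / (lA * lB)."""
    if lA < 1 or lB < 1:
        raise ValueError("chain lengths must be >= 1")
    return S / (lA * lB)


def core_coverage(n_matched: int, Ac: int, Bc: int) -> float:
    """CORE-COV: matched SSE count over the smaller structure's SSE count."""
    smaller = min(Ac, Bc)
    if n_matched > smaller:
        raise ValueError(
            f"matched count {n_matched} exceeds smaller core count {smaller}"
        )
    if smaller == 0:
        return 0.0
    return n_matched / smaller


def best_alignment(
    topk: list[RankedIndependentSet],
    score_matrix: ScoreMatrix,
    G,
    H,
    sequential: bool = True,
) -> Alignment:
    """Pick the alignment with the best raw score S among the top-K sets.

    Ties go to the larger set, then to the lexicographically smallest
    member tuple, so selection is deterministic.  Sn and CORE-COV are
    filled from the two graphs.
    """
    if not topk:
        raise ValueError("topk must be non-empty")
    best = None
    best_key = None
    for rs in topk:
        S = alignment_score(list(rs.pairs), score_matrix)
        key = (-S, -rs.cardinality, tuple(sorted(rs.members)))
        if best_key is None or key < best_key:
            best, best_key, best_S = rs, key, S
    pairs = sorted(best.pairs)
    return Alignment(
        matched_pairs=pairs,
        pair_scores=[score_matrix[p] for p in pairs],
        S=best_S,
        Sn=normalized_score(best_S, G.length, H.length),
        core_cov=core_coverage(len(pairs), G.n_sses, H.n_sses),
        sequential=sequential,
        a_id=G.protein_id,
        b_id=H.protein_id,
    )


def compare_structures(
    A: ProteinStructure,
    B: ProteinStructure,
    r: int = DEFAULT_R,
    K: int = DEFAULT_K,
    sequential: bool = True,
    trim_min_score: float | None = None,
) -> Alignment:
    """Full comparison pipeline for two structures.

    The structure with fewer SSEs acts as the query (its SSE count bounds
    the auxiliary graph at r*n vertices); the reported pairs are always
    oriented (A index, B index).  Steps: score all same-kind SSE pairs,
    keep the top-r candidates per query SSE, build the conflict graph
    (optionally trimmed), enumerate the top-K maximal independent sets,
    and return the best-S alignment.
    """
    swap = B.graph.n_sses < A.graph.n_sses
    Q, T = (B, A) if swap else (A, B)
    score_matrix = compute_score_matrix(Q.graph, T.graph, Q.residues, T.residues)
    pairs = top_r_candidates(Q.graph, T.graph, r, Q.residues, T.residues,
                             score_matrix=score_matrix)
    X = build_auxiliary_graph(pairs, Q.graph, T.graph, sequential=sequential)
    logger.info("auxiliary graph: %d vertices, %d edges (bound r*n = %d)",
                X.n_vertices, len(X.edges), r * Q.graph.n_sses)
    if trim_min_score is not None:
        X = trim_auxiliary_graph(X, min_score=trim_min_score)
    topk = enumerate_top_k(X, K)
    logger.info("enumerated %d of up to %d independent sets", len(topk), K)
    aln = best_alignment(topk, score_matrix, Q.graph, T.graph,
                         sequential=sequential)
    if swap:
        flipped = sorted(
            ((a, b), s)
            for (b, a), s in zip(aln.matched_pairs, aln.pair_scores)
        )
        aln = Alignment(
            matched_pairs=[p for p, _ in flipped],
            pair_scores=[s for _, s in flipped],
            S=aln.S, Sn=aln.Sn, core_cov=aln.core_cov,
            sequential=aln.sequential, a_id=aln.b_id, b_id=aln.a_id,
        )
    return aln


def rank_database(
    query: ProteinStructure,
    db: list[tuple[str, ProteinStructure]],
    r: int = DEFAULT_R,
    K: int = DEFAULT_K,
    sequential: bool = True,
    trim_min_score: float | None = None,
) -> list[tuple[str, float, float]]:
    """Compare the query against every database entry and rank by Sn.

    Returns (entry id, Sn, core_cov) rows sorted by Sn descending, ties
    by CORE-COV descending then id.  Per-entry failures are logged and
    skipped so one bad entry never aborts a scan.
    """
    if not db:
        raise ValueError("database is empty")
    rows: list[tuple[str, float, float]] = []
    for name, target in db:
        try:
            aln = compare_structures(query, target, r=r, K=K,
                                     sequential=sequential,
                                     trim_min_score=trim_min_score)
        except Exception:
            logger.exception("comparison against %s failed; skipped", name)
            continue
        rows.append((name, aln.Sn, aln.core_cov))
    rows.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return rows
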