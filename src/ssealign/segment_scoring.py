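"""Residue-segment similarity and SSE-pair scoring.

The similarity of two Calpha-Calpha distances d1, d2 is

    D(d1, d2) = 0.1 - |d1 - d2| / (d1 + d2)

which lies in (-0.9, 0.1] and equals 0.1 exactly when d1 = d2.  The
residue-pair score ``L_ij`` compares the local segment around residue *i*
of protein A with the segment around residue *j* of protein B:

    L_ij = min{ D(d^A[i-2,i+2], d^B[j-2,j+2]),
                D(d^A[i-2,i+1], d^B[j-2,j+1]),
                D(d^A[i-1,i+2], d^B[j-1,j+2]) }

where d^X[p,q] is the Calpha distance between positions p and q of chain
X.  The score of an SSE pair is the best ungapped sum of L_ij over the
aligned residues, and each query SSE keeps its top-r scoring partners as
candidate mappings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ssealign.structure_graph import SSE, MixedStructureGraph, Residue

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class CandidatePair:
    """A permitted mapping of query SSE ``g_index`` to host SSE ``h_index``."""

    g_index: int
    h_index: int
    score: float


@dataclass
class ScoreMatrix:
    """SSE-pair scores keyed by (query index, host index).

    Only same-kind pairs are present; cross-kind mappings are excluded by
    the mixed-graph model's vertex typing.
    """

    entries: dict[tuple[int, int], float]

    def __getitem__(self, key: tuple[int, int]) -> float:
        return self.entries[key]

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self.entries

    def to_tsv(self) -> str:
        rows = ["g_index\th_index\tscore"]
        for (g, h), s in sorted(self.entries.items()):
            rows.append(f"{g}\t{h}\t{s:.6f}")
        return "\n".join(rows) + "\n"


def ca_distance(residues: list[Residue], p: int, q: int) -> float:
    """Euclidean Calpha distance between chain positions p and q (1-based)."""
    n = len(residues)
    if not (1 <= p <= n and 1 <= q <= n):
        raise IndexError(f"residue position out of range: {p}, {q} (chain has {n})")
    return float(np.linalg.norm(residues[p - 1].xyz - residues[q - 1].xyz))


def d_similarity(d1: float, d2: float) -> float:
    """Distance-pair similarity ``0.1 - |d1 - d2| / (d1 + d2)``.

    Defined as 0.1 when both distances are zero (identical degenerate
    segments); negative distances are rejected.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("distances must be non-negative")
    if d1 + d2 == 0:
        return 0.1
    return 0.1 - abs(d1 - d2) / (d1 + d2)


#: The three (p-offset, q-offset) windows compared by L_ij.
_WINDOWS = ((-2, 2), (-2, 1), (-1, 2))


def l_ij(resA: list[Residue], resB: list[Residue], i: int, j: int) -> float:
    """Local segment similarity of position i in chain A vs j in chain B.

    Windows reaching past a chain end are dropped; the value is the
    minimum over the in-range windows, or 0 when no window fits.
    """
    nA, nB = len(resA), len(resB)
    terms = []
    for lo, hi in _WINDOWS:
        pa, qa = i + lo, i + hi
        pb, qb = j + lo, j + hi
        if 1 <= pa and qa <= nA and 1 <= pb and qb <= nB:
            dA = ca_distance(resA, pa, qa)
            dB = ca_distance(resB, pb, qb)
            terms.append(d_similarity(dA, dB))
    if not terms:
        return 0.0
    return min(terms)


def sse_pair_score(
    A_sse: SSE, B_sse: SSE, resA: list[Residue], resB: list[Residue]
) -> float:
    """Score of one SSE pair: best ungapped residue correspondence.

    The shorter element (m residues) slides along the longer without gaps;
    each offset sums L_ij over the m aligned residue pairs and the maximum
    over offsets is returned.  Comparing a helix with a strand is an error.
    """
    if A_sse.kind != B_sse.kind:
        raise ValueError(
            f"SSE kind mismatch: {A_sse.kind} vs {B_sse.kind}"
        )
    la, lb = len(A_sse), len(B_sse)
    m = min(la, lb)
    best = -np.inf
    for off in range(abs(la - lb) + 1):
        off_a = off if la >= lb else 0
        off_b = off if lb > la else 0
        total = 0.0
        for k in range(m):
            i = A_sse.start_res + off_a + k
            j = B_sse.start_res + off_b + k
            total += l_ij(resA, resB, i, j)
        best = max(best, total)
    return float(best)


def compute_score_matrix(
    G: MixedStructureGraph,
    H: MixedStructureGraph,
    resG: list[Residue],
    resH: list[Residue],
) -> ScoreMatrix:
    """All same-kind SSE-pair scores between query G and host H."""
    entries: dict[tuple[int, int], float] = {}
    for g in G.sses:
        for h in H.sses:
            if g.kind == h.kind:
                entries[(g.index, h.index)] = sse_pair_score(g, h, resG, resH)
    return ScoreMatrix(entries)


def top_r_candidates(
    G: MixedStructureGraph,
    H: MixedStructureGraph,
    r: int,
    resG: list[Residue],
    resH: list[Residue],
    score_matrix: ScoreMatrix | None = None,
) -> list[CandidatePair]:
    """For each query SSE, its r best same-kind host SSEs.

    Ties break toward the lower host index; output is ordered by query
    index then rank, so repeated runs are identical.  A query SSE with no
    same-kind partner contributes no pairs.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if score_matrix is None:
        score_matrix = compute_score_matrix(G, H, resG, resH)
    pairs: list[CandidatePair] = []
    for g in G.sses:
        scored = [
            (score_matrix[(g.index, h.index)], h.index)
            for h in H.sses
            if h.kind == g.kind
        ]
        if not scored:
            logger.info("query SSE %d (%s) has no same-kind partner in %s",
                        g.index, g.kind, H.protein_id)
            continue
        scored.sort(key=lambda t: (-t[0], t[1]))
        for score, h_index in scored[:r]:
            pairs.append(CandidatePair(g_index=g.index, h_index=h_index,
                                       score=score))
    return pairs
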