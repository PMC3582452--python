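"""Mixed structure-graph representation of a protein chain.

A chain is reduced to its secondary structure elements (SSEs).  The mixed
graph ``G = (V, A, E)`` has one vertex per SSE, an implicit arc path
``0 -> 1 -> ... -> n-1`` following N-to-C chain order, and an undirected
edge between two SSEs whenever they are in spatial contact (minimum
inter-Calpha distance below a threshold).
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

HELIX = "helix"
STRAND = "strand"

#: DSSP codes accepted as core element codes.  Only pure alpha helix (H) and
#: extended strand (E) count; 3-10/pi helices (G, I) and isolated bridges (B)
#: are treated as loop so that toy fixtures stay predictable.
HELIX_CODES = frozenset("H")
STRAND_CODES = frozenset("E")

#: Minimum run lengths for a run of codes to become an SSE.
MIN_HELIX_LEN = 4
MIN_STRAND_LEN = 3

#: Default contact threshold in Angstrom for an interaction edge.
DEFAULT_CONTACT_THRESHOLD = 8.0


@dataclass(frozen=True)
class Residue:
    """One residue with its Calpha position.

    ``seq_index`` is the author residue number from the coordinate file
    (1-based, strictly increasing along the chain).  Scoring functions
    address residues by their 1-based *position* in the chain list, which
    for generated fixtures coincides with ``seq_index``.
    """

    seq_index: int
    ca_xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise ValueError(f"seq_index must be >= 1, got {self.seq_index}")
        if not np.all(np.isfinite(self.ca_xyz)):
            raise ValueError("Calpha coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.ca_xyz, dtype=float)


@dataclass
class SSE:
    """A core element: one helix or strand.

    ``start_res``/``end_res`` are 1-based inclusive positions in the chain.
    ``residues`` is empty for graph-only representations (exchange files,
    random graphs) that carry no coordinates.
    """

    index: int
    kind: str
    start_res: int
    end_res: int
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in (HELIX, STRAND):
            raise ValueError(f"unknown SSE kind {self.kind!r}")
        if self.start_res > self.end_res:
            raise ValueError("SSE span inverted")

    def __len__(self) -> int:
        return self.end_res - self.start_res + 1


@dataclass
class MixedStructureGraph:
    """The triple (V, A, E) of the mixed-graph model.

    ``sses`` defines the vertex set and, through its order, the arc path;
    ``interaction_edges`` holds the undirected contact edges as sorted
    index pairs; ``length`` is the residue count of the chain (used for
    score normalization).
    """

    protein_id: str
    sses: list[SSE]
    interaction_edges: set[tuple[int, int]]
    length: int

    def __post_init__(self) -> None:
        n = len(self.sses)
        canon = set()
        for i, j in self.interaction_edges:
            if i == j:
                raise ValueError("self-loop interaction edge")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) outside vertex range 0..{n - 1}")
            canon.add((min(i, j), max(i, j)))
        self.interaction_edges = canon
        for k, sse in enumerate(self.sses):
            if sse.index != k:
                raise ValueError("SSE indices must be 0..n-1 in order")

    @property
    def n_sses(self) -> int:
        return len(self.sses)

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.interaction_edges

    def kinds(self) -> list[str]:
        return [s.kind for s in self.sses]

    def to_json(self) -> str:
        return json.dumps(
            {
                "protein_id": self.protein_id,
                "length": self.length,
                "sses": [
                    {"index": s.index, "kind": s.kind,
                     "start": s.start_res, "end": s.end_res}
                    for s in self.sses
                ],
                "edges": sorted(self.interaction_edges),
            },
            indent=2,
        )


@dataclass
class ProteinStructure:
    """Bundle of a mixed structure graph and the chain's residues."""

    graph: MixedStructureGraph
    residues: list[Residue]

    @classmethod
    def from_pdb_dssp(
        cls,
        pdb_text: str,
        dssp_text: str,
        chain_id: str = "A",
        protein_id: str | None = None,
        contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    ) -> "ProteinStructure":
        residues = parse_pdb_chain(pdb_text, chain_id)
        codes = parse_dssp(dssp_text, chain_id)
        if len(codes) != len(residues):
            warnings.warn(
                f"DSSP has {len(codes)} residues but PDB chain has "
                f"{len(residues)}; truncating to the shorter"
            )
            m = min(len(codes), len(residues))
            codes, residues = codes[:m], residues[:m]
        spans = segment_sses(codes)
        sses = [
            SSE(index=k, kind=kind, start_res=a, end_res=b,
                residues=residues[a - 1:b])
            for k, (kind, a, b) in enumerate(spans)
        ]
        graph = build_structure_graph(
            residues, sses, contact_threshold=contact_threshold,
            protein_id=protein_id or "protein",
        )
        return cls(graph=graph, residues=residues)


def parse_pdb_chain(pdb_text: str, chain_id: str) -> list[Residue]:
    """Extract the Calpha trace of one chain from PDB-format text.

    Returns one :class:`Residue` per residue that has a CA atom, in file
    order.  Alternate locations resolve to the first occurrence (lowest
    altloc identifier); residues lacking a CA atom are skipped with a
    logged warning.  A chain absent from the file is an error.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Atom import DisorderedAtom

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError("no models in PDB input") from None
    if chain_id not in model:
        raise ValueError(f"chain {chain_id!r} not found in PDB input")
    chain = model[chain_id]

    residues: list[Residue] = []
    for res in chain:
        if res.id[0] != " ":  # skip heteroatoms and waters
            continue
        if "CA" not in res:
            logger.warning(
                "residue %s%s has no CA atom; skipped", res.resname, res.id[1]
            )
            continue
        atom = res["CA"]
        if isinstance(atom, DisorderedAtom):
            atom = min(atom.disordered_get_list(), key=lambda a: a.get_altloc())
        x, y, z = (float(v) for v in atom.coord)
        residues.append(Residue(seq_index=res.id[1], ca_xyz=(x, y, z)))
    if not residues:
        raise ValueError(f"chain {chain_id!r} contains no CA atoms")
    return residues


def parse_dssp(dssp_text: str, chain_id: str) -> str:
    """Read per-residue secondary structure codes from classic DSSP output.

    The classic layout places data lines after the ``#  RESIDUE`` header
    with the chain identifier in column 12 and the summary code in column
    17 (1-based).  Chain-break lines (``!`` in the amino-acid column) are
    skipped.  The returned string has one code per residue of the chain in
    file order, aligned with :func:`parse_pdb_chain` output.
    """
    lines = dssp_text.splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line:
            start = k + 1
            break
    if start is None:
        raise ValueError("malformed DSSP input: missing '#  RESIDUE' header")

    codes: list[str] = []
    for line in lines[start:]:
        if len(line) < 14:
            continue
        if line[13] == "!":  # chain break
            continue
        if line[11] != chain_id:
            continue
        codes.append(line[16] if len(line) > 16 else " ")
    return "".join(codes)


def segment_sses(ss_codes: str) -> list[tuple[str, int, int]]:
    """Segment a per-residue code string into SSE spans.

    Maximal runs of helix codes of length >= 4 and strand codes of length
    >= 3 become elements; everything else is loop.  Spans are returned as
    ``(kind, start, end)`` with 1-based inclusive positions, in N-to-C
    order.
    """
    spans: list[tuple[str, int, int]] = []
    i, n = 0, len(ss_codes)
    while i < n:
        c = ss_codes[i]
        if c in HELIX_CODES or c in STRAND_CODES:
            kind = HELIX if c in HELIX_CODES else STRAND
            group = HELIX_CODES if kind == HELIX else STRAND_CODES
            j = i
            while j < n and ss_codes[j] in group:
                j += 1
            run = j - i
            minlen = MIN_HELIX_LEN if kind == HELIX else MIN_STRAND_LEN
            if run >= minlen:
                spans.append((kind, i + 1, j))
            i = j
        else:
            i += 1
    return spans


def build_structure_graph(
    residues: list[Residue],
    sses: list[SSE] | list[tuple[str, int, int]],
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    protein_id: str = "protein",
) -> MixedStructureGraph:
    """Assemble the mixed graph from a chain and its SSE spans.

    An interaction edge ``{i, j}`` is present iff the minimum distance
    between any Calpha of SSE *i* and any Calpha of SSE *j* is at most
    ``contact_threshold`` (Angstrom).
    """
    if sses and not isinstance(sses[0], SSE):
        sses = [
            SSE(index=k, kind=kind, start_res=a, end_res=b,
                residues=residues[a - 1:b])
            for k, (kind, a, b) in enumerate(sses)
        ]
    coords = [np.array([r.xyz for r in s.residues]) for s in sses]
    for k, c in enumerate(coords):
        if c.size == 0:
            raise ValueError(f"SSE {k} has no residues; cannot compute contacts")
    edges: set[tuple[int, int]] = set()
    for i in range(len(sses)):
        for j in range(i + 1, len(sses)):
            if cdist(coords[i], coords[j]).min() <= contact_threshold:
                edges.add((i, j))
    return MixedStructureGraph(
        protein_id=protein_id,
        sses=list(sses),
        interaction_edges=edges,
        length=len(residues),
    )


# ---------------------------------------------------------------------------
# Plain-text graph exchange format
#
#   # ssegraph v1
#   protein <id> length <residue count>
#   sse <index> <kind> <start> <end>
#   ...
#   edge <i> <j>
#   ...
# ---------------------------------------------------------------------------

def write_graph_file(graph: MixedStructureGraph) -> str:
    """Serialize a graph (topology only, no coordinates) to exchange text."""
    out = ["# ssegraph v1",
           f"protein {graph.protein_id} length {graph.length}"]
    for s in graph.sses:
        out.append(f"sse {s.index} {s.kind} {s.start_res} {s.end_res}")
    for i, j in sorted(graph.interaction_edges):
        out.append(f"edge {i} {j}")
    return "\n".join(out) + "\n"


def read_graph_file(text: str) -> MixedStructureGraph:
    """Parse the exchange format written by :func:`write_graph_file`.

    Duplicate SSE indices and edges referencing unknown vertices are
    errors.  The resulting graph carries no coordinates.
    """
    protein_id, length = "protein", 0
    sses: list[SSE] = []
    seen_idx: set[int] = set()
    edges: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "protein":
            protein_id = parts[1]
            if len(parts) >= 4 and parts[2] == "length":
                length = int(parts[3])
        elif tag == "sse":
            idx, kind, a, b = int(parts[1]), parts[2], int(parts[3]), int(parts[4])
            if idx in seen_idx:
                raise ValueError(f"line {lineno}: duplicate SSE index {idx}")
            seen_idx.add(idx)
            sses.append(SSE(index=idx, kind=kind, start_res=a, end_res=b))
        elif tag == "edge":
            edges.add((int(parts[1]), int(parts[2])))
        else:
            raise ValueError(f"line {lineno}: unknown record {tag!r}")
    sses.sort(key=lambda s: s.index)
    n = len(sses)
    if seen_idx and seen_idx != set(range(n)):
        raise ValueError("SSE indices must form 0..n-1")
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i},{j}) references unknown SSE index")
    if length == 0:
        length = sum(len(s) for s in sses) or 1
    return MixedStructureGraph(
        protein_id=protein_id, sses=sses, interaction_edges=edges, length=length
    )
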