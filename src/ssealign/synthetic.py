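"""Idealized toy structures and random mixed graphs for testing.

Toy proteins are Calpha-only chains built from ideal elements: helices as
spirals with a 1.5 A rise per residue, 2.3 A radius and 100 degrees of
turn per residue; strands as straight traces with a 3.5 A step.  Three
loop residues are interpolated between consecutive elements.  The
matching DSSP-format text is emitted alongside the coordinates, so the
full parsing pipeline can run with no downloads.  All generators are
deterministic per seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from ssealign.structure_graph import (
    HELIX,
    STRAND,
    MixedStructureGraph,
    ProteinStructure,
)
from ssealign.reductions import bare_graph

HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TURN_DEG = 100.0
STRAND_STEP = 3.5
LOOP_LEN = 3
MIN_LEN = {HELIX: 4, STRAND: 3}

#: Element spec entry: (kind, length, origin or None, axis or None)
ElementSpec = tuple


@dataclass
class ToyProtein:
    """A generated structure: PDB text, DSSP text, and ground truth."""

    pdb_text: str
    dssp_text: str
    ss_codes: str
    coords: np.ndarray
    chain_id: str
    element_spans: list[tuple[str, int, int]]

    def to_structure(self, protein_id: str = "toy",
                     contact_threshold: float = 8.0) -> ProteinStructure:
        return ProteinStructure.from_pdb_dssp(
            self.pdb_text, self.dssp_text, chain_id=self.chain_id,
            protein_id=protein_id, contact_threshold=contact_threshold,
        )


def _frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    u = u / norm
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return u, e1, e2


def helix_coords(n: int, origin, axis) -> np.ndarray:
    """Ideal alpha-helix Calpha trace of n residues starting at origin."""
    u, e1, e2 = _frame(axis)
    origin = np.asarray(origin, dtype=float)
    theta = np.deg2rad(HELIX_TURN_DEG) * np.arange(n)
    return (
        origin
        + np.outer(HELIX_RISE * np.arange(n), u)
        + HELIX_RADIUS * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
    )


def strand_coords(n: int, origin, axis) -> np.ndarray:
    """Straight strand trace of n residues with a 3.5 A step."""
    u, _, _ = _frame(axis)
    origin = np.asarray(origin, dtype=float)
    return origin + np.outer(STRAND_STEP * np.arange(n), u)


def _element_coords(kind: str, length: int, origin, axis) -> np.ndarray:
    if kind == HELIX:
        return helix_coords(length, origin, axis)
    if kind == STRAND:
        return strand_coords(length, origin, axis)
    raise ValueError(f"unknown element kind {kind!r}")


def _extent(kind: str, length: int) -> float:
    step = HELIX_RISE if kind == HELIX else STRAND_STEP
    return step * (length - 1)


def _place_elements(spec, rng) -> list[tuple[str, np.ndarray]]:
    """Resolve a spec into element Calpha arrays.

    Entries with explicit origin and axis are honoured verbatim; the rest
    are centred on a jittered line with generous gaps so unrelated
    elements neither overlap nor fall within contact range.
    """
    placed: list[tuple[str, np.ndarray]] = []
    cursor = 0.0
    for entry in spec:
        kind, length = entry[0], int(entry[1])
        origin = entry[2] if len(entry) > 2 else None
        axis = entry[3] if len(entry) > 3 else None
        if length < MIN_LEN[kind]:
            raise ValueError(
                f"{kind} of length {length} is below the SSE minimum "
                f"{MIN_LEN[kind]}"
            )
        if origin is not None and axis is not None:
            coords = _element_coords(kind, length, origin, axis)
        else:
            ext = _extent(kind, length)
            center_x = cursor + ext / 2.0 + 20.0
            cursor = center_x + ext / 2.0
            center = np.array([
                center_x,
                rng.uniform(-6.0, 6.0),
                rng.uniform(-6.0, 6.0),
            ])
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords = _element_coords(kind, length, center - u * ext / 2.0, u)
        placed.append((kind, coords))
    for a in range(len(placed)):
        for b in range(a + 1, len(placed)):
            d = np.linalg.norm(
                placed[a][1][:, None, :] - placed[b][1][None, :, :], axis=-1
            ).min()
            if d < 2.0:
                raise ValueError(
                    f"elements {a} and {b} overlap (min distance {d:.2f} A)"
                )
    return placed


def _assemble_chain(
    placed: list[tuple[str, np.ndarray]]
) -> tuple[np.ndarray, str, list[tuple[str, int, int]]]:
    coords: list[np.ndarray] = []
    codes: list[str] = []
    spans: list[tuple[str, int, int]] = []
    pos = 0
    for e, (kind, xyz) in enumerate(placed):
        if e > 0:
            prev_end = coords[-1][-1]
            nxt = xyz[0]
            fracs = (np.arange(1, LOOP_LEN + 1) / (LOOP_LEN + 1))[:, None]
            loop = prev_end + fracs * (nxt - prev_end)
            coords.append(loop)
            codes.append(" " * LOOP_LEN)
            pos += LOOP_LEN
        spans.append((kind, pos + 1, pos + len(xyz)))
        coords.append(xyz)
        codes.append(("H" if kind == HELIX else "E") * len(xyz))
        pos += len(xyz)
    if not coords:
        raise ValueError("empty element spec")
    return np.vstack(coords), "".join(codes), spans


def write_pdb(coords: np.ndarray, chain_id: str = "A") -> str:
    """Serialize a Calpha trace as PDB text (one ALA CA atom per residue)."""
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("toy")
    sb.init_model(0)
    sb.init_chain(chain_id)
    sb.init_seg("    ")
    for i, xyz in enumerate(coords, start=1):
        sb.init_residue("ALA", " ", i, " ")
        sb.init_atom("CA", np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                     " CA ", i, "C")
    out = io.StringIO()
    pdbio = PDBIO()
    pdbio.set_structure(sb.get_structure())
    pdbio.save(out)
    return out.getvalue()


def write_dssp(ss_codes: str, chain_id: str = "A") -> str:
    """Serialize per-residue codes as classic DSSP-format text."""
    lines = [
        "==== Secondary Structure Definition, synthetic idealized trace ====",
        "REFERENCE generated fixture",
        f"{len(ss_codes):5d}  1  0  0  0 TOTAL NUMBER OF RESIDUES",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
    ]
    for i, code in enumerate(ss_codes, start=1):
        lines.append(f"{i:5d}{i:5d} {chain_id} A  {code}")
    return "\n".join(lines) + "\n"


def toy_protein(spec, seed: int = 0, chain_id: str = "A") -> ToyProtein:
    """Generate an idealized protein from an element spec.

    ``spec`` is a list of (kind, length[, origin, axis]) entries; entries
    without placement are positioned automatically (deterministic per
    seed).  Returns PDB and DSSP text plus the ground-truth spans.
    """
    rng = np.random.default_rng(seed)
    placed = _place_elements(spec, rng)
    coords, codes, spans = _assemble_chain(placed)
    return ToyProtein(
        pdb_text=write_pdb(coords, chain_id),
        dssp_text=write_dssp(codes, chain_id),
        ss_codes=codes,
        coords=coords,
        chain_id=chain_id,
        element_spans=spans,
    )


def random_mixed_graph(
    n: int,
    edge_prob: float,
    kind_prob: float = 0.5,
    seed: int = 0,
) -> MixedStructureGraph:
    """A coordinate-free random mixed graph with Bernoulli contact edges."""
    rng = np.random.default_rng(seed)
    kinds = [HELIX if rng.random() < kind_prob else STRAND for _ in range(n)]
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < edge_prob
    }
    return bare_graph(n, edges, protein_id=f"random-{seed}", kinds=kinds)


@dataclass
class PlantedPair:
    """A query and a target that contains the query's elements verbatim."""

    query: ToyProtein
    target: ToyProtein
    mapping: dict[int, int]


def plant_common_structure(
    query_spec,
    target_padding: int | tuple[int, int],
    seed: int = 0,
) -> PlantedPair:
    """Embed a query structure inside a larger target.

    The target chain consists of padding elements, the query's elements
    with identical geometry, then more padding.  Padding elements are
    placed far from the core (no spurious contacts) and their lengths
    avoid the query's element lengths so the planted mapping is the
    unambiguous optimum.  Ground truth: query SSE i maps to target SSE
    i + n_before.
    """
    if isinstance(target_padding, int):
        before = target_padding // 2
        after = target_padding - before
    else:
        before, after = target_padding
    rng = np.random.default_rng(seed)
    core = _place_elements(query_spec, rng)
    core_coords = np.vstack([c for _, c in core])
    x_min = core_coords[:, 0].min()
    x_max = core_coords[:, 0].max()

    used_lengths = {
        (kind, coords.shape[0]) for kind, coords in core
    }

    def padding_element(slot: int, x_center: float):
        kind = HELIX if rng.random() < 0.5 else STRAND
        choices = [
            ln for ln in range(MIN_LEN[kind], 15)
            if (kind, ln) not in used_lengths
        ]
        length = int(rng.choice(choices))
        used_lengths.add((kind, length))
        ext = _extent(kind, length)
        center = np.array([x_center,
                           rng.uniform(-6.0, 6.0),
                           rng.uniform(-6.0, 6.0)])
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        return (kind, _element_coords(kind, length, center - u * ext / 2.0, u))

    placed_before = [
        padding_element(i, x_min - 50.0 - 35.0 * (before - 1 - i))
        for i in range(before)
    ]
    placed_after = [
        padding_element(i, x_max + 50.0 + 35.0 * i) for i in range(after)
    ]
    target_placed = placed_before + core + placed_after

    q_coords, q_codes, q_spans = _assemble_chain(core)
    t_coords, t_codes, t_spans = _assemble_chain(target_placed)
    query = ToyProtein(
        pdb_text=write_pdb(q_coords), dssp_text=write_dssp(q_codes),
        ss_codes=q_codes, coords=q_coords, chain_id="A",
        element_spans=q_spans,
    )
    target = ToyProtein(
        pdb_text=write_pdb(t_coords), dssp_text=write_dssp(t_codes),
        ss_codes=t_codes, coords=t_coords, chain_id="A",
        element_spans=t_spans,
    )
    mapping = {i: i + before for i in range(len(core))}
    return PlantedPair(query=query, target=target, mapping=mapping)
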