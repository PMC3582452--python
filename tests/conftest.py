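import numpy as np
import pytest

from ssealign.auxiliary_graph import AuxiliaryGraph
from ssealign.segment_scoring import CandidatePair


def make_aux(n, edges, scores=None):
    """Bare auxiliary graph over n vertices for enumeration tests."""
    scores = scores if scores is not None else [0.0] * n
    verts = [CandidatePair(k, k, float(scores[k])) for k in range(n)]
    return AuxiliaryGraph(vertices=verts, edges=set(edges))


def toy_spec(i):
    """Deterministic varied element spec for fixture protein i.

    Proteins differ in SSE count (2-5) and element lengths, with lengths
    distinct within each kind so candidate scores discriminate."""
    rng = np.random.default_rng(1000 + i)
    n = 2 + i % 4
    helix_lengths = list(rng.permutation(np.arange(5, 13)))
    strand_lengths = list(rng.permutation(np.arange(4, 11)))
    spec = []
    for _ in range(n):
        kind = "helix" if rng.random() < 0.5 else "strand"
        length = int(helix_lengths.pop() if kind == "helix"
                     else strand_lengths.pop())
        spec.append((kind, length))
    return spec


@pytest.fixture(scope="session")
def toy_proteins():
    """Twenty generated toy structures, parsed through the full pipeline."""
    from ssealign import synthetic

    prots = []
    for i in range(20):
        toy = synthetic.toy_protein(toy_spec(i), seed=i)
        prots.append((f"p{i:02d}", toy.to_structure(f"p{i:02d}")))
    return prots
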