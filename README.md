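# ssealign

SSE-based protein structure comparison by top-K maximum independent set
enumeration.

`ssealign` is for structural bioinformaticians who want fast, flexible
comparison of protein folds at the level of secondary structure elements
(SSEs) — including **non-sequential** alignments, substructure/motif
detection inside larger structures, and inspection of near-optimal
alternative alignments — without residue-level superposition.

## The model

A protein chain is reduced to a **mixed graph** `G = (V, A, E)`:

* `V` — one vertex per core element (α-helix or β-strand, typed),
* `A` — arcs forming the N→C path `0 → 1 → … → n−1` (chain order),
* `E` — undirected edges between SSEs whose minimum inter-Cα distance is
  ≤ 8 Å (spatial contacts).

Comparing two structures means finding a maximum common subgraph of the
two mixed graphs under per-vertex candidate lists. Candidates are scored
from local backbone geometry: for Cα–Cα distances

```
D(d1, d2) = 0.1 − |d1 − d2| / (d1 + d2)            ∈ (−0.9, 0.1]
L_ij = min{ D(d^A_{i−2,i+2}, d^B_{j−2,j+2}),
            D(d^A_{i−2,i+1}, d^B_{j−2,j+1}),
            D(d^A_{i−1,i+2}, d^B_{j−1,j+2}) }
```

and an SSE pair's score is the best ungapped sum of `L_ij` over its
aligned residues. Each query SSE keeps its top-`r` partners; every
candidate mapping `g_i → h_j` becomes a vertex `x_ij` of an **auxiliary
conflict graph**, with edges whenever two mappings collide (shared
vertex), cross chain order (dropped in non-sequential mode), or lose a
contact edge. Independent sets of this graph are exactly the valid
partial alignments, so the **top-K maximal independent sets** (branch and
bound with an exhaustive oracle for validation) are the K best candidate
alignments. The winner maximizes the raw score `S = Σ pair scores`;
database ranking uses `Sn = S / (l_A · l_B)` and
`CORE-COV = matched / min(A_c, B_c)`.

Two exactness guarantees round the method out: when every candidate list
has at most two entries the embedding decision is solved in polynomial
time by a 2-CNF-SAT reduction (`ssealign.two_sat`), and a CLIQUE
reduction (`ssealign.reductions`) generates ground-truthed hard instances
that tie the whole pipeline to brute-force oracles.

## Worked example

Generate a toy query and a larger target with the query planted inside
(3 extra padding SSEs), then align:

```sh
ssealign simulate planted --spec "helix:10,strand:5,strand:6" \
    --padding 3 --seed 7 --out-prefix plant
ssealign compare plant.query.pdb plant.query.dssp \
    plant.target.pdb plant.target.dssp
```

prints

```
a_index	b_index	a_span	b_span	pair_score
0	1	1-10	14-23	0.9000
1	2	14-18	27-31	0.5000
2	3	22-27	35-40	0.5000
# S=1.9000 Sn=0.00103486 CORE-COV=100%
```

All three query SSEs are matched (CORE-COV 100%) onto target SSEs 1–3 —
exactly where the generator planted them, skipping the padding element at
index 0. Each pair score is 0.1 per scorable residue (the `L_ij`
self-similarity value), and `Sn` divides `S = 1.9` by the product of the
chain lengths (27 × 68). Searching a small database ranks by `Sn`:

```
rank	id	Sn	core_cov
1	self	0.00260631	100%
2	host0	0.00103486	100%
3	other	0.000658704	33%
```

— the query retrieves its exact copy first, then the structure embedding
it, then an unrelated fold.

The same pipeline is available as a library (`ssealign.compare_structures`,
`ssealign.rank_database`), and `ssealign embed` solves exact whole-graph
embedding (2-SAT route with `--width2`, independent-set route otherwise).

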