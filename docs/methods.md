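# Methods

## The mixed-graph model and its assumptions

A protein chain is represented by its secondary structure elements only.
The mixed graph `G = (V, A, E)` keeps three kinds of information: vertex
type (helix vs strand), chain order (the arc set is always the spanning
path `0 → 1 → … → n−1`, so order reduces to index comparison), and
spatial contacts (undirected edges). Everything finer — loop geometry,
side chains, residue identity — is deliberately discarded; the model
assumes that fold similarity is captured by which typed elements exist,
in what order, and which ones touch.

Contacts are defined by the minimum inter-Cα distance between two
elements with an 8.0 Å cutoff. The cutoff is configurable
(`contact_threshold`); 8 Å is the conventional Cα contact radius and all
shipped defaults use it. SSE assignment is taken from a DSSP file, never
recomputed from geometry: runs of `H` of length ≥ 4 become helices and
runs of `E` of length ≥ 3 become strands, while 3₁₀/π helices (`G`, `I`)
and isolated bridges (`B`) count as loop. These minima keep one-residue
assignment noise from spawning spurious vertices and make toy fixtures
predictable; they are package choices, stated here because no single
standard exists.

## Scoring

The segment similarity `D(d1, d2) = 0.1 − |d1 − d2|/(d1 + d2)` compares
two intra-chain Cα–Cα distances; it is symmetric, at most 0.1, and equals
0.1 exactly on identical distances. The residue-pair score `L_ij` takes
the minimum of three `D` terms over ±2-residue windows around residue
`i` of one chain and `j` of the other. Two boundary rules are ours:
windows that would leave the chain are dropped and the minimum runs over
the remaining terms (a residue with no valid window contributes 0), and
degenerate zero/zero distance pairs score 0.1. Both keep every SSE
scorable near chain ends without changing interior values.

The score of an SSE pair slides the shorter element along the longer
without gaps and keeps the best offset's sum of `L_ij`. Only same-kind
pairs are scored — the vertex typing of the model makes helix↔strand
mappings meaningless. Per query SSE the top `r` partners survive (ties to
the lower host index), so the auxiliary graph has at most `r·n` vertices,
`n` being the smaller structure's SSE count; the smaller structure is
always taken as the query.

## Auxiliary graph and enumeration

Vertex `x_ij` stands for the mapping `g_i → h_j`; edges join mappings
that cannot coexist: (1) shared query or host vertex, (2) crossing chain
order — applied in both orientations, since conflict edges are
undirected — and (3) a query contact whose images are not in contact.
Dropping rule (2) yields non-sequential alignment; the non-sequential
edge set is a subset of the sequential one, so optima can only grow.
`verify_alignment` re-checks any pair subset directly against the
embedding conditions without the auxiliary graph, and the test suite
asserts exhaustively (all subsets of small instances, both modes) that
independence and validity coincide.

Trimming of low-scoring candidate vertices exists (`min_score` or a
per-query `keep_fraction`) but is **off by default**: any trimming rule
changes which top-K sets are reachable, so it is an explicit opt-in
filter rather than a hidden heuristic.

"Top-K maximum independent sets" is read as the K best *maximal*
independent sets under the total order (cardinality desc, total score
desc, lexicographic vertex tuple asc) — this keeps K = 1000 meaningful
when the maximum is unique, and makes output order total and
reproducible. The enumerator walks maximal independent sets as maximal
cliques of the complement graph (pivoted Bron–Kerbosch-style branching on
integer bitsets) and prunes any branch whose optimistic bound |R| + |P|
falls below the current K-th best cardinality; pruning on cardinality
alone is safe because sets smaller than the K-th best can never enter the
top K, while equal-size sets (which may win on score) are kept. Scores
are summed in sorted member order so equal sets always produce bitwise
equal floats, which the oracle-agreement tests rely on. A guarded
subset-scan oracle (≤ 20 vertices, hard error beyond) validates the
enumerator on hundreds of random graphs. Typical comparison-sized
instances (≈ 40-vertex sparse conflict graphs) enumerate K = 1000 sets in
well under a second.

The best alignment among the top K maximizes the raw score `S`; ties go
to the larger set, then the lexicographically smallest member tuple. `Sn
= S/(l_A·l_B)` is used only for cross-protein ranking, where length
normalization matters; within one pair it is a monotone transform of
`S`. `Sn`'s product normalization is unusual (many methods divide by a
square root of the length product); it is implemented exactly as defined,
and the alternative is noted here only. `CORE-COV` is the matched count
over the smaller structure's SSE count, reported as a whole percentage in
CLI output and a fraction in the API.

## The width-2 exact route

When every candidate list has at most two entries, embedding is decided
in polynomial time by translation to 2-CNF: one variable per (vertex,
image) pair; clause family (a) makes the map well defined, (b) excludes
image collisions and order violations for every ordered vertex pair, (c)
excludes landing a query contact on a host non-contact. The solver builds
the implication graph and tests strongly connected components (networkx
provides the SCC step); assignments follow the reverse-topological rule,
so they are deterministic. Decoded maps are re-verified before being
returned.

`verify_embedding` accepts an order-condition mode: `iff` (whole-graph
embedding, order agreement in both directions) and `forward` (the partial
variant). Because arc sets are spanning paths the orders are total, and
for injective maps the two modes provably coincide; both are kept because
they mirror the two problem definitions, not because they can disagree
here — a witness would need non-path arc sets, which the data model
excludes.

## Ground-truthed hard instances

The CLIQUE reduction builds width-1 instances whose valid partial
embeddings are exactly the cliques of an arbitrary input graph: query
edges complete, host edges the input's, identity lists. Brute-force
clique search, brute-force embedding search (an exhaustive DFS over
subsets and list choices, valid because the conditions are hereditary;
hard-guarded at 12 query vertices), and the independent-set pipeline must
all agree — the strongest end-to-end consistency check in the suite.

## Synthetic fixtures: what they emulate and what they do not

Toy proteins are ideal Cα traces: helices with 1.5 Å rise, 2.3 Å radius,
100°/residue; strands straight at 3.5 Å/residue; 3-residue interpolated
loops between elements (long enough to keep the ±2 scoring windows
populated near element boundaries). Unconstrained elements are placed
≥ 20 Å apart with jitter, so unrelated elements are never in contact and
— because the scoring windows see each element's loop context — same-kind
elements of equal length still score distinguishably. Fixture specs drawn
for the test suite use distinct element lengths per kind, making the
self- and planted-alignment optima unique. Planted instances copy the
query's elements verbatim into a larger chain with remote padding whose
lengths avoid the query's, recording the ground-truth mapping.

What passing these tests shows: the machinery recovers a planted common
substructure exactly, ranks exact and embedding hosts first, and behaves
monotonically in `r` and `K`. What it does not show: performance on real
folds, where elements bend, contacts are ambiguous, DSSP boundaries are
noisy, and near-duplicate elements create genuine score ties. Real-data
accuracy depends on the contact threshold and any trimming applied, and
is not certified by this suite.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r` | 5 | candidate partners kept per query SSE (auxiliary graph ≤ r·n vertices) |
| `K` | 1000 | maximal independent sets enumerated |
| `contact_threshold` | 8.0 Å | minimum inter-Cα distance defining an interaction edge |
| `sequential` | true | enforce chain order; false enables non-sequential alignment |
| trimming | off | opt-in candidate filter (`min_score` or per-query `keep_fraction`) |

`r` and `K` defaults follow the method's standard operating point;
raising either can only improve (never worsen) the best raw score, a
monotonicity the tests assert. Problem sizes in the shipped tests —
random conflict graphs up to 15 vertices for exhaustive oracles, 20
fixture proteins of 2–5 SSEs, planted targets up to ~9 SSEs — were chosen
so every exhaustive cross-check runs comfortably at desk scale while
still exercising all branching paths of the enumerator.

## Known limitations

* Single chain per comparison; mmCIF and multi-model inputs are out of
  scope, and SSE assignment requires a DSSP file or the graph exchange
  format.
* The intra-SSE correspondence is ungapped; bulged strands or kinked
  helices are scored as rigid blocks.
* Score ties between geometrically identical elements are resolved by
  deterministic index-based tie-breaks, not by geometry.
* Worst-case enumeration time is exponential in the auxiliary graph size;
  `r` and trimming are the practical controls.
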