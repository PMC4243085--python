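# Methods

## Model

An uncertain network is a simple graph `g = (V, E, p)` with
`p : E → (0, 1]`.  Probability 0 is excluded by construction: an edge
that certainly does not exist is simply absent, and the circuit
construction below needs strictly positive conductances.  Node labels
are opaque strings; any biological annotation is carried through I/O but
never enters the algorithms.  Directed input is accepted at the data
level; circuits are always built on the symmetrized graph (a resistive
circuit has no edge direction), while adjacency mismatches compare the
directed adjacency when direction is flagged.

**Probability isomorphism.**  Graphs `g`, `g′` on `k` nodes are
probability-isomorphic when some bijection of their nodes makes the
total absolute difference of corresponding edge probabilities at most
`θ` (absent edges count as probability 0), optionally with every single
difference at most `α`.  The mismatch `PMval` is summed over *ordered*
index pairs, so for undirected graphs each edge difference is counted
twice; `θ` defaults are calibrated to that convention and the doubling
is deliberate — it keeps the formula identical for directed graphs.

## Associated circuit and voltage signature

Each edge of probability `p` becomes a resistor of resistance `1/p`
(conductance `p`).  Grounding node `i` and injecting a unit current into
each of the other `k−1` nodes ("complete excitation") gives the reduced
node-voltage system `G·U = 1`, where `G` is the `(k−1)×(k−1)` principal
submatrix of the weighted Laplacian: diagonal = sum of incident edge
probabilities, off-diagonal = −p(u,v).  For a connected graph with
positive probabilities `G` is symmetric positive definite, so the solve
(dense `scipy.linalg.solve`, `assume_a="pos"`; `k ≤ ~8` in practice)
cannot fail and all voltages are strictly positive.  Sorting the `k−1`
voltages ascending gives the sequence `Sᵢ`; stacking all `k` choices of
reference node gives the voltage matrix `S`, a node invariant —
relabeling the graph permutes the rows but changes no entry.  Linearity
gives a useful exact property: scaling all probabilities by `c` scales
every voltage by `1/c`.

The right-hand side is +1 for every non-reference node.  The excitation
wording ("currents from the reference toward the others") leaves the
sign convention open; the +1 convention is fixed because it reproduces
the reference voltage table exactly (the opposite sign flips all
voltages negative).

**Augmentation.**  Optionally (default on) each row of `S` is extended
with its mean and population variance (divisor `k−1`, the sequence
length — the row is the complete set of voltages for that reference,
not a sample).  This sharpens the voltage filter at no additional solve
cost; the reference-table checks use the raw, unaugmented rows.

## Alignment and decision procedure

`Dist(i, j)` is the squared Euclidean distance between row `i` of `S`
and row `j` of `S′` (no square root — the quadratic-form expansion is
used literally; only the threshold scale is affected and `ε` is
user-set).  `scipy.optimize.linear_sum_assignment` solves the
assignment problem; the optimal cost is `VMval`, the minimum total
row-mismatch over all bijections.

The staged test:

1. **Voltage filter.**  `VMval > ε` ⇒ not isomorphic.  This is the
   necessary-condition direction: probability-isomorphic graphs have
   similar circuits, hence similar voltage signatures.  (One printed
   statement of this branch in the source material is inverted relative
   to its own surrounding prose; the prose semantics — reject when the
   mismatch *exceeds* the threshold — is the only reading consistent
   with the necessary-condition theorem and is what is implemented.)
2. **Hungarian mapping.**  Under the optimal assignment, accept if
   `PMval ≤ θ` (and, in strict mode, every `|Δ| ≤ α`).
3. **Permutation fallback.**  The optimal voltage assignment need not be
   the best adjacency alignment, so remaining bijections are searched in
   lexicographic order with branch-and-bound pruning (a partial ordered-
   pair mismatch already above `θ`, or a pair difference above `α` in
   strict mode, prunes the subtree), returning on the first success.
   The search is capped at `max_permutation_k = 8` nodes and raises a
   refusal error beyond it.

All comparisons use an absolute tolerance of 1e−9.  With `ε = θ = 0`
the procedure reduces to exact weighted-graph isomorphism: identical
graphs under relabeling give `VMval = PMval = 0`.

The per-edge `α` check is off by default: it is expensive relative to
its value once the voltage filter is in place, and the sum criterion
`θ` is the operative one; a strict mode re-enables it inside the
accepting stages.  `brute_force_iso` (exhaustive over `k! ≤ 8!`
bijections, checking both `α` and `θ`) serves as the reference decision
in the test suite, never in the pipeline.

## Candidate enumeration

ESU enumeration produces every connected `k`-subset exactly once, in a
deterministic order given the node order; a brute-force subset filter
is the test oracle.  Induced-subgraph semantics are used (all host edges
among the `k` nodes), the standard motif convention.  Only non-tree
subgraphs (edge count ≥ `k`) are kept as candidates, since the patterns
of biological interest contain cycles and tree candidates dominate the
count without adding them.  The partition-based search cited for this
step elsewhere is not documented anywhere reproducible; ESU is exact
and well-understood, and only the candidate *set* matters downstream.
An optional `max_instances` cap aborts cleanly on combinatorial
blow-up.

## Two-step clustering

Clusters start as singletons in candidate order.  **Phase 1**: with
`L_c` active clusters, pair cluster `i` with cluster `i + ⌈L_c/2⌉` for
`i = 1..⌊L_c/2⌋` (the middle element of an odd list is carried forward —
the loop bound alone does not define odd behaviour, so this is fixed
here); each pair that passes the isomorphism test is merged; passes
repeat until one completes with no merge.  No pairwise structure is ever
materialized — memory stays linear in the number of active clusters.
**Phase 2**: classical agglomeration on the residual clusters, merging
the pair of representatives with smallest `VMval` that passes the full
test, until no pair passes.  A lazy min-heap keyed by `VMval` with
stale-entry discarding implements this; since heap order is `VMval`
order, the loop can stop as soon as the smallest remaining `VMval`
exceeds `ε`.  Cluster representatives cache their voltage matrices, so
each representative's circuit is solved once.

**Merging.**  The union of two clusters is under-defined in the
abstract, so the representative is the support-weighted mean of the two
aligned probability adjacencies, `(n_a·A + n_b·B_mapped)/(n_a + n_b)` —
it stays a valid probability graph and tracks the cluster centroid.
Where one graph has an edge the other lacks, the mean keeps the edge at
a reduced probability.  A `strict_merge` flag keeps the first member as
representative instead, for comparisons against the most literal
reading.  Members record their host node sets, so every pattern remains
traceable to network locations.

Support is the member count; clusters with support ≥ `min_sup` are
reported, sorted by descending support (ties in first-seen order), each
with frequency = support / candidate count.  No frequency threshold is
applied *during* clustering — support filtering is post hoc only.
Determinism contract: identical input, configuration and seed give
byte-identical reports (sorted JSON keys, 9-significant-digit floats).

## Default thresholds

`ε = θ = ln(k(k−1))` per subgraph scale `k` (≈ 2.485 at `k = 4`) — the
empirical upper limit at which clusters remain coherent while their
number stays small.  Raising either threshold can only turn
non-isomorphic verdicts isomorphic (monotonicity), so cluster counts
decrease as thresholds grow.

## Synthetic data

The generator emulates a confidence-scored interaction network:
`n_edges` background edges sampled uniformly among node pairs with
probabilities drawn from `probability_law`, default
`uniform(0.3, 1.0)` — the shape of a network *pre-filtered at a
confidence cutoff*, the common practice of discarding low-score
interactions before analysis.  Planted pattern copies occupy disjoint
node sets (so ground-truth membership is unambiguous); each copy
overwrites the background topology on its nodes and jitters the
pattern's probabilities by independent uniform noise in `±jitter`,
clipped to `[0.01, 1]` so probabilities never leave `(0, 1]`.  All
randomness flows through a single seeded `numpy.random.default_rng`.

What the generator does *not* emulate: real degree distributions
(hubs), directed regulatory structure, overlapping pattern instances,
and correlated probability noise.  Passing recovery tests therefore
demonstrates the pipeline's mechanics, not performance on real PPI
data.

**A regime worth knowing about.**  At the default thresholds, two
same-topology background subgraphs whose probabilities are confined to
a narrow band are usually probability-isomorphic *by definition* (at
`k = 4`, θ ≈ 2.485 while two random 5-edge graphs with probabilities in
(0.3, 1) differ by ≈ 2.3 in expectation).  The background then chains
into large clusters whose averaged representatives drift, and in a
minority of seeds this splits the planted instances across two
clusters: the measured all-6-instance recovery rate at the default
generator settings (40 nodes, 60 background edges, 6 copies, jitter
0.01) is 16/20 seeds.  With a wider probability spread — uniform(0.05,1)
or beta(1.5,1.5) backgrounds — the background stops being self-similar
at θ and recovery is 20/20.  This is a property of the loose default
thresholds interacting with narrow probability ranges (the clustering's
documented bias under permissive thresholds), not of the isomorphism
core: in every seed all planted pairs are mutually probability-
isomorphic, and on well-separated mixtures (two patterns, 20 jittered
copies each, no background) the clustering recovers exactly the two
ground-truth groups.

## Problem sizes

The test suite and the reproduction script run at the scales the method
targets in practice for unit verification: subgraph scales `k = 3..5`,
hosts up to 40 nodes / ~90 edges (~200 four-node candidates), 100–200
random pairs per oracle sweep, 20 generator seeds for recovery.  Runtime
is seconds on one core; the dominant cost is the per-pair Hungarian
alignment in clustering.

## Known limitations

- Highly symmetric graphs admit many optimal voltage assignments; the
  Hungarian step returns one deterministically, and the permutation
  fallback covers the rest only up to `k ≤ 8`.
- The voltage filter is a necessary condition: `ε` too small can reject
  genuinely isomorphic pairs whose probability noise moves voltages; the
  `ε = θ = ln(k(k−1))` defaults err permissive.
- Cluster results depend on candidate order (both phases are
  order-dependent by construction); the order is deterministic, so runs
  are reproducible, but a different candidate order can yield a
  different clustering of borderline pairs.
- Motif *significance* (comparison against randomized networks) is out
  of scope; the output is frequent patterns, the input to such an
  analysis.
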