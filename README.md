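# upm — frequent probability-pattern mining in uncertain biological networks

Biological interaction networks are rarely certain: protein–protein
interactions and regulatory bindings come with confidence scores, so the
natural data model is an *uncertain graph* — a simple graph `g = (V, E, p)`
whose every edge carries an existence probability `p ∈ (0, 1]`.  Finding
recurring wiring patterns (the precursor to motif analysis) in such a
network requires a notion of isomorphism that tolerates probability noise,
and a way to avoid the `2^|E|` possible-world explosion.

`upm` implements that pipeline for network biologists:

1. **Candidate enumeration** — all connected, non-tree (cycle-containing)
   `k`-node induced subgraphs, via exact ESU enumeration.
2. **Probability isomorphism** — two `k`-node probability graphs are
   probability-isomorphic when some node bijection keeps the total
   absolute edge-probability difference `Σ|Δᵢⱼ| ≤ θ` (optionally each
   `|Δᵢⱼ| ≤ α`).  Instead of testing all `k!` bijections, each graph is
   turned into its *associated circuit*: every edge becomes a resistor of
   conductance `p`.  With node `i` grounded and 1 A injected into every
   other node, solving the reduced node-voltage system `G·U = I` gives an
   ascending voltage sequence `Sᵢ`; the `k` sequences form a
   relabeling-invariant signature matrix `S`.  The Hungarian algorithm on
   the squared-Euclidean distance matrix between the rows of `S` and `S′`
   yields the minimum voltage mismatch `VMval` — a cheap necessary
   condition (`VMval > ε` rejects) — and a candidate node mapping under
   which the adjacency mismatch `PMval = Σ|p − p′|` decides against `θ`,
   with a pruned permutation search as fallback.
3. **Frequent patterns** — two-step hierarchical clustering groups the
   candidates: stride-paired merging passes to a fixpoint, then classical
   smallest-`VMval` agglomeration; clusters with support `≥ min_sup` are
   the frequent patterns.  Default thresholds are `ε = θ = ln(k(k−1))`.

A seeded synthetic-network generator (random background + planted,
probability-jittered pattern copies with ground truth) makes the whole
pipeline testable without any external data.

## Worked example

The bundled 4-node reference graph has edges
`v1–v2 0.92, v2–v3 0.97, v2–v4 0.94, v3–v4 0.1, v1–v4 1.0`.

```python
import upm

g = upm.example4_graph()
print(upm.voltage_matrix(g, augment=False))
```

```
[[1.41364173 1.72430246 2.62984819]
 [1.0345041  1.06919391 1.07770516]
 [2.72695385 3.54854767 3.67570063]
 [1.27797752 1.580127   2.36703102]]
```

Row `i` is the ascending voltage sequence with node `i` as reference —
e.g. grounding `v4` gives `S₄ = (1.277978, 1.580127, 2.367031)`.  An
exact relabeling is accepted even at zero thresholds, with zero voltage
and adjacency mismatch:

```python
h = g.relabeled({"v1": "a", "v2": "b", "v3": "c", "v4": "d"})
upm.iso_test(g, h, upm.IsoThresholds(epsilon=0.0, theta=0.0))
# IsoVerdict(isomorphic=True, vmval=0.0, pmval=0.0,
#            mapping=(0, 1, 2, 3), stage='hungarian-accept')
```

The same from the shell, end to end — generate a 40-node network with 6
planted copies of the reference pattern, then mine 4-node patterns:

```sh
upm generate --nodes 40 --edges 60 --pattern example4 --copies 6 \
    --jitter 0.01 --seed 1 --out net.tsv --truth truth.json
# wrote 88 edges on 40 nodes to net.tsv
upm mine --input net.tsv --k 4 --min-sup 5 --out patterns.json
# mined 199 candidates -> 12 frequent pattern(s)
```

`patterns.json` lists each frequent pattern with its support, frequency
(support / candidates), representative probability graph (the aligned,
support-weighted mean of its members) and member node sets; for this
seed the top cluster has support 32 (frequency 0.161, mean member
`PMval` 0.585 against the representative).  `upm iso` and
`upm voltages` expose the pairwise decision and the raw voltage
signatures for individual graphs.

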