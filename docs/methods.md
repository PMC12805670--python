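# Methods

## Problem

Given rooted phylogenetic trees `T_1, …, T_k` — possibly multifurcating and
on overlapping taxon subsets — construct a rooted phylogenetic network `N`
that displays every `T_i` and has small hybridization number
`h(N) = Σ_{v ≠ root} (indeg(v) − 1)`. A tree `T` is **hard-displayed** when
some resolution of the reticulations, restricted to `T`'s taxa, is
isomorphic to `T`; it is **soft-displayed** when that restriction merely
refines `T` (multifurcations may be resolved). All networks produced here
are **tree-child**: every non-leaf node has a child with in-degree one.
Finding the minimum is NP-hard; this package is a heuristic.

## Encoding

Fix a total order `π` on the union taxon set. After normalising each tree to
a root of out-degree one, label every node: the root with the tree's π-least
taxon, each leaf with its own taxon, each bifurcation with the larger of the
two child minima, each multifurcation with the set of child minima minus the
least. Every taxon of the tree then occurs exactly once internally and once
as a leaf; the labels along the path between the two occurrences form its
**lineage taxon hypersequence** (row). A row always starts and ends with the
taxon's singleton; interior entries are π-greater than the row's taxon,
which is what makes decoding acyclic.

Decoding maps each element of each row to a node, chains a row's elements,
connects every foreign member of an element to the head of that member's
row, and suppresses in/out-degree-one nodes. Reticulations arise only at row
heads, hence tree-child output. The hybridization number equals
`Σ_{x ≠ π-min} (refs(x) − 1)` where `refs(x)` counts occurrences of `x` in
other taxa's rows. A merged encoding in which some non-minimal taxon is
unreferenced is repaired by inserting one reference into the row of the
largest π-smaller taxon sharing a tree with it.

## Alignment

For each taxon the rows of all trees are merged into a common
super-hypersequence. Elements match iff one contains the other, and a match
emits the superset; a mismatch is not a legal transition rather than a
finite penalty. The pairwise problem is solved exactly by dynamic
programming (match 0, gap 1, deterministic tie-breaking); more rows are
folded progressively in input order. For the final evaluation of the chosen
ordering a uniform-cost search computes the exact cheapest merge per taxon
(cost = foreign members emitted), with the progressive result as fallback
when the state space exceeds 200 000 index vectors. On the benchmark
instances the exact and progressive merges almost always agree; the exact
pass is kept because it makes the exhaustive-search mode attain the
brute-force optimum by construction.

## Ordering search

`h` depends strongly on `π`. The greedy search fixes positions left to
right, trying every unplaced taxon at the next position with the remaining
taxa in current order, and keeps the minimiser (O(n²) evaluations per pass).
Passes are repeated for `rounds = 10` with early stopping after
`patience = 3` passes without improvement. Because a pass is idempotent from
its own output, later rounds diversify: odd rounds restart from a fresh
seeded shuffle, even rounds from the incumbent perturbed by an escalating
number of random transpositions. The best ordering is polished by a
first-improvement relocation local search. For ≤ 8 taxa an exhaustive mode
scores every permutation.

Two reductions shrink the search space recursively: maximal congruent
subtrees (same taxa, same topology in every tree containing them) are
replaced by formal taxa, and a largest common cluster (size ≥ 3) splits the
problem into an "above" and a "within" instance; solved subnetworks are
grafted back in place of the formal leaves.

## Soft-display heuristics

Before encoding, trees are mutually refined (clusters of other trees are
inserted into compatible multifurcations) and any tree soft-displayed by
another input on its own is dropped. At the encoding level, the refinement
rewrite resolves a set-valued element toward a taxon supported by another
tree, and the add-leaf rewrite grafts a taxon missing from a tree using a
shared neighbour. During fusion both rewrites are accepted only when they do
not increase the hybridization number of the merged encoding.

## Synthetic instances

The generator mirrors how discordant gene trees arise: a 500-taxon random
background tree (uniform random joins), a seed tree induced by a random
taxon subset, and `k` input trees each obtained from the seed tree by a
given number of nontrivial rooted subtree-prune-and-regraft (rSPR) moves,
optionally degraded by contracting a proportion `c` of internal edges and
deleting a proportion `m` of taxa. With one rSPR per tree, some network
soft-displaying all `k` inputs has `h ≤ k` — but that witness network need
not be tree-child when moves interact, so a tree-child heuristic can
legitimately land slightly above `k` on individual instances; published
evaluations of this protocol average over samples. All randomness flows
through `numpy.random.default_rng`, with derived sub-seeds below 2³¹.

## Parameter and scale choices

* Search defaults: `rounds = 10`, `patience = 3`, search seed 0, wall-clock
  guard 900 s per instance.
* Support threshold: off by default; `--support 70` contracts internal edges
  with bootstrap below 70 % (values in [0, 1] are treated as fractions).
* Display checks enumerate at most 2²⁰ reticulation resolutions and refuse
  beyond that.
* The brute-force optimum oracle is limited to ≤ 6 taxa and ≤ 3 trees; the
  exhaustive ordering mode to ≤ 8 taxa.
* Test-suite problem sizes — 500 round-trip trees up to 50 taxa, 100 fused
  instances up to 5 trees × 30 taxa, 20 single-rSPR pairs, one 10-tree ×
  50-taxon bound instance — are the package's chosen verification scale.

## Limitations

* The hybridization number is heuristic: the ordering search is greedy and
  the per-taxon merges are computed independently, so the result can exceed
  the tree-child optimum, and the tree-child optimum itself can exceed the
  best unconstrained network.
* Hard display of heavily multifurcating inputs can be impossible to improve
  once the soft heuristics have rewritten the encoding; verification should
  use soft display in that regime.
* Branch lengths and support values are parsed but only support values are
  used (for optional contraction); output networks carry topology only.
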