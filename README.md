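# phylofuse

Fuse rooted phylogenetic trees into a **tree-child rooted phylogenetic
network** that displays every input tree while keeping the number of
reticulations (the *hybridization number*) small.

Gene trees estimated from different loci routinely disagree — through
hybridization, horizontal gene transfer, reassortment, or simply estimation
error — and a rooted network with a few reticulate nodes can summarise a
whole collection of such trees in one structure. `phylofuse` implements the
PhyloFusion approach, an extension of the ALTS algorithm to input trees that
may contain **multifurcations** (unresolved nodes) and **missing taxa**
(trees on overlapping but unequal taxon sets).

## How it works

1. **Encoding.** Under a total order on the taxa, every tree is encoded as
   one *lineage taxon hypersequence* (LTH) per taxon: the node labels read
   along the path from the taxon's internal occurrence to its leaf.
   Multifurcations contribute set-valued elements; bifurcating trees yield
   plain strings.
2. **Alignment.** For each taxon, the rows from all trees are merged into a
   common super-hypersequence by progressive pairwise alignment (match =
   containment, mismatch forbidden, gap cost 1). Every extra reference to a
   taxon in the merged rows costs one reticulation.
3. **Decoding.** The merged encoding decodes into a rooted network whose
   reticulate nodes all sit at row heads — which makes the result tree-child
   by construction — and which displays every input tree.
4. **Search.** The hybridization number depends on the taxon ordering, so a
   greedy search fixes one position at a time, with diversified restarts and
   a relocation local search. Common subtrees and common clusters are
   factored out first and fused recursively.

Two preprocessing steps (mutual refinement, removal of trees displayed by
other inputs) and two encoding-level rewrites (refinement and add-leaf
heuristics) close the gap between *hard* display, which preserves
multifurcations exactly, and the biologically more relevant *soft* display.

## Library quickstart

```python
>>> import phylofuse as pf
>>> trees = pf.read_newick("((a,b),c);\n((a,c),b);")   # one rSPR apart
>>> result = pf.fuse(trees)
>>> result.h
1
>>> pf.write_enewick(result.network)
'((((a,(c)#H1),b),#H1));'
>>> bool(pf.displays_hard(result.network, trees[0]))
True
```

The encoding layer is exposed directly:

```python
>>> ordering = pf.TaxonOrdering(list("abc"))
>>> enc = pf.encode_lth(pf.normalize_root(trees[0]), ordering)
>>> print(pf.format_encoding(enc))
a: a c b a
b: b b
c: c c
```

## Command line

```sh
phylofuse simulate --taxa 50 --trees 10 --seed 1 --out trees.nwk
phylofuse fuse --trees trees.nwk --out network.enwk
phylofuse verify network.enwk trees.nwk
```

`fuse` accepts `--support <pct>` to contract weakly supported edges first,
`--seed`/`--rounds`/`--patience` to control the ordering search, and
`--json` for machine-readable summaries. Networks are written in extended
Newick (`#H` tags); exit codes are 0 (ok), 1 (validation), 2 (timeout),
3 (internal).

## Testing and reproduction

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates the two headline quantities from scratch:
the median hybridization number over twenty single-rSPR tree pairs
(expected 1), and the hybridization number for an instance of ten trees one
rSPR each from a 50-taxon seed tree, where any network soft-displaying all
inputs needs at most ten reticulations. See `docs/methods.md` for the model,
parameter choices, and known limitations.
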