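"""Top-level fusion of rooted trees into a tree-child network.

The pipeline per taxon ordering is: encode every tree as lineage taxon
hypersequences, optionally rewrite the encodings with the soft-display
heuristics, merge the per-taxon rows by progressive alignment into an SCH
encoding, repair any unreferenced taxon, and read the hybridization
number off the reference counts.  A greedy O(n^2) search over taxon
orderings fixes one position at a time, keeping the taxon that minimises
the hybridization number; whole passes are rerun for a configurable
number of rounds with early stopping.  The driver is recursive: common
subtrees and common clusters are factored out as formal taxa first and
grafted back into the final network.
"""

from __future__ import annotations

import itertools
import logging
import math
import random
import time
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from . import softheur
from .alignment import exact_sch, progressive_sch
from .encoding import (
    LTHEncoding,
    TaxonOrdering,
    decode,
    encode_lth,
    reference_counts,
)
from .treeio import (
    PhyloNetwork,
    PhyloTree,
    TreeNode,
    TreeValidationError,
    contract_low_support,
    normalize_root,
    restrict,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FusionConfig",
    "FusionResult",
    "evaluate_ordering",
    "greedy_ordering_search",
    "subtree_reduction",
    "cluster_reduction",
    "fuse",
]


@dataclass(frozen=True)
class FusionConfig:
    """Search and heuristic parameters.

    ``rounds`` greedy passes are run, stopping early after ``patience``
    passes without improvement.  ``timeout`` is a wall-clock guard in
    seconds per instance; when it expires the best network found so far
    is returned.
    """

    rounds: int = 10
    patience: int = 3
    cluster_reduction: bool = True
    refine_heuristic: bool = True
    add_leaf_heuristic: bool = True
    seed: int = 0
    support_threshold: Optional[float] = None
    exhaustive_orderings: bool = False
    timeout: float = 900.0

    def __post_init__(self):
        if self.rounds < 1 or self.patience < 1:
            raise ValueError("rounds and patience must be >= 1")


@dataclass
class FusionResult:
    network: PhyloNetwork
    h: int
    ordering: TaxonOrdering
    rounds_used: int


# ----------------------------------------------------------------------
# scoring an ordering


def _merge_encodings(encodings: Sequence[LTHEncoding],
                     ordering: TaxonOrdering,
                     exact: bool = False) -> LTHEncoding:
    """Per-taxon SCH merge, then decodability repair.

    The merge is progressive alignment by default (fast, used inside the
    ordering search) or the exact uniform-cost search when ``exact`` is
    set (used for final evaluation; falls back to progressive alignment
    when the exact state space is too large).  A taxon that is locally
    minimal in every tree containing it but not globally minimal ends up
    unreferenced; one reference is inserted after the head of the row of
    the largest smaller taxon that shares a tree with it (falling back
    to the globally minimal taxon's row).
    """
    rows: dict[str, tuple] = {}
    for x in ordering.taxa:
        parts = [e.rows[x] for e in encodings if x in e.rows]
        if parts:
            merged = exact_sch(parts, x) if exact else None
            rows[x] = merged if merged is not None else progressive_sch(parts)
    taxa = [t for t in ordering.taxa if t in rows]
    refs = reference_counts(rows)
    for x in taxa[1:]:
        if refs.get(x, 0) > 0:
            continue
        sharing = set()
        for enc in encodings:
            if x in enc.rows:
                sharing.update(enc.rows)
        candidates = [w for w in sharing
                      if ordering.key(w) < ordering.key(x)]
        w = max(candidates, key=ordering.key) if candidates else taxa[0]
        row = list(rows[w])
        row.insert(1, frozenset({x}))
        rows[w] = tuple(row)
        logger.debug("decodability repair: referencing %s from row %s", x, w)
    return LTHEncoding(ordering, rows)


def _h_of_rows(merged: LTHEncoding) -> int:
    refs = reference_counts(merged.rows)
    taxa = merged.taxa()
    return sum(refs[x] - 1 for x in taxa[1:])


def _heuristics_applicable(encodings: Sequence[LTHEncoding]) -> bool:
    taxa_sets = [frozenset(e.rows) for e in encodings]
    if len(set(taxa_sets)) > 1:
        return True
    return any(len(el) > 1 for e in encodings
               for row in e.rows.values() for el in row)


def _score_ordering(trees: Sequence[PhyloTree], ordering: TaxonOrdering,
                    config: Optional[FusionConfig],
                    exact: bool = False) -> tuple[int, LTHEncoding]:
    encodings = [encode_lth(t, ordering) for t in trees]
    use_heur = (config is not None
                and (config.refine_heuristic or config.add_leaf_heuristic)
                and len(trees) > 1
                and _heuristics_applicable(encodings))
    if use_heur:
        current = [_h_of_rows(_merge_encodings(encodings, ordering))]

        def accept(candidate: list[LTHEncoding]) -> bool:
            h = _h_of_rows(_merge_encodings(candidate, ordering))
            if h <= current[0]:
                current[0] = h
                return True
            return False

        if config.refine_heuristic:
            encodings = softheur.refine_heuristic(encodings, accept=accept)
        if config.add_leaf_heuristic:
            encodings = softheur.add_leaf_heuristic(encodings, accept=accept)
    merged = _merge_encodings(encodings, ordering)
    if exact:
        alt = _merge_encodings(encodings, ordering, exact=True)
        if _h_of_rows(alt) < _h_of_rows(merged):
            merged = alt
    return _h_of_rows(merged), merged


def evaluate_ordering(trees: Sequence[PhyloTree], ordering: TaxonOrdering,
                      config: Optional[FusionConfig] = None
                      ) -> tuple[PhyloNetwork, int]:
    """Encode, align, decode one ordering; returns (network, h).

    Uses the exact per-taxon merge when feasible, keeping whichever of
    the exact and progressive merges yields the lower hybridization
    number.
    """
    h, merged = _score_ordering(trees, ordering, config, exact=True)
    network = decode(merged)
    return network, h


# ----------------------------------------------------------------------
# ordering search


def _greedy_pass(trees, order: list[str], config, deadline: float
                 ) -> tuple[list[str], int]:
    cur = list(order)
    n = len(cur)
    h_final = None
    for p in range(n):
        best_h = math.inf
        best_idx = p
        for idx in range(p, n):
            cand = cur[:p] + [cur[idx]] + cur[p:idx] + cur[idx + 1:]
            h, _ = _score_ordering(trees, TaxonOrdering(cand), config)
            if h < best_h:
                best_h, best_idx = h, idx
            if time.monotonic() > deadline:
                break
        cur = cur[:p] + [cur[best_idx]] + cur[p:best_idx] + cur[best_idx + 1:]
        h_final = best_h
        if time.monotonic() > deadline:
            break
    return cur, int(h_final)


def _relocation_local_search(trees, order: list[str], h: int, config,
                             deadline: float) -> tuple[list[str], int]:
    """First-improvement hill climb over single-taxon relocations.

    Repeatedly tries moving one taxon to another position, restarting
    the sweep on every improvement, until a full sweep finds none or the
    deadline expires.
    """
    cur, cur_h = list(order), h
    n = len(cur)
    improved = True
    while improved and time.monotonic() <= deadline:
        improved = False
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                cand = list(cur)
                cand.insert(j, cand.pop(i))
                cand_h, _ = _score_ordering(trees, TaxonOrdering(cand), config)
                if cand_h < cur_h:
                    cur, cur_h = cand, cand_h
                    improved = True
                    break
                if time.monotonic() > deadline:
                    return cur, cur_h
            if improved:
                break
    return cur, cur_h


def greedy_ordering_search(trees: Sequence[PhyloTree],
                           config: Optional[FusionConfig] = None
                           ) -> FusionResult:
    """Greedy position-by-position ordering search.

    Each pass fixes positions 1..n one at a time, trying every unplaced
    taxon at the next position with the remaining taxa in current order
    and keeping the minimiser (ties keep the earliest taxon).  A pass is
    idempotent from its own result, so later rounds diversify: they
    alternate between a fresh seeded shuffle of the taxa and the best
    ordering perturbed by a number of random transpositions that grows
    with the stagnation count.  With ``config.exhaustive_orderings``
    every permutation is tried instead (guarded to n <= 8).
    """
    if config is None:
        config = FusionConfig()
    union = sorted(set().union(*(t.taxa() for t in trees)))
    deadline = time.monotonic() + config.timeout

    if config.exhaustive_orderings:
        if len(union) > 8:
            raise ValueError("exhaustive ordering search limited to n <= 8")
        best_h, best_order = math.inf, None
        for perm in itertools.permutations(union):
            h, _ = _score_ordering(trees, TaxonOrdering(perm), config)
            if h < best_h:
                best_h, best_order = h, list(perm)
            if best_h == 0 or time.monotonic() > deadline:
                break
        ordering = TaxonOrdering(best_order)
        net, h = evaluate_ordering(trees, ordering, config)
        return FusionResult(net, h, ordering, rounds_used=1)

    rng = random.Random(config.seed)
    best_h = math.inf
    best_order: Optional[list[str]] = None
    start = list(union)
    no_improve = 0
    rounds_used = 0
    for _ in range(config.rounds):
        rounds_used += 1
        order, h = _greedy_pass(trees, start, config, deadline)
        logger.debug("round %d: h = %d", rounds_used, h)
        if h < best_h:
            best_h, best_order = h, order
            no_improve = 0
        else:
            no_improve += 1
        if best_h == 0 or no_improve >= config.patience:
            break
        if time.monotonic() > deadline:
            logger.warning("ordering search stopped by timeout")
            break
        if len(union) > 1 and rounds_used % 2 == 1:
            start = list(union)
            rng.shuffle(start)
        else:
            start = list(best_order)
            for _ in range(min(no_improve + 1, len(start) // 2)):
                i, j = rng.sample(range(len(start)), 2)
                start[i], start[j] = start[j], start[i]
    if best_h > 0:
        best_order, best_h = _relocation_local_search(
            trees, best_order, best_h, config, deadline)
    ordering = TaxonOrdering(best_order)
    net, h = evaluate_ordering(trees, ordering, config)
    return FusionResult(net, h, ordering, rounds_used=rounds_used)


# ----------------------------------------------------------------------
# reductions


def _fresh_names(existing: frozenset, count: int, stem: str = "F") -> list[str]:
    names = []
    i = 1
    while len(names) < count:
        name = f"{stem}__{i}"
        if name not in existing:
            names.append(name)
        i += 1
    return names


def _qualifying_common_subtrees(trees: Sequence[PhyloTree]) -> list[frozenset]:
    """Taxon sets of rooted subtrees congruent across all relevant trees."""
    all_clusters = [t.clusters() for t in trees]
    all_taxa = [t.taxa() for t in trees]
    candidates = set()
    for clusters in all_clusters:
        candidates.update(c for c in clusters if len(c) >= 2)
    qualifying = []
    for C in candidates:
        topo = None
        ok = True
        for clusters, taxa in zip(all_clusters, all_taxa):
            if not taxa & C:
                continue
            if not C <= taxa or C not in clusters:
                ok = False
                break
            sub = frozenset(cl for cl in clusters if cl <= C)
            if topo is None:
                topo = sub
            elif sub != topo:
                ok = False
                break
        if ok:
            qualifying.append(C)
    return qualifying


def _replace_clade(tree: PhyloTree, cluster: frozenset,
                   name: str) -> Optional[PhyloTree]:
    """Replace the clade on ``cluster`` by a leaf ``name``; None if absent."""
    nodes = _clusters_to_nodes(tree)
    node = nodes.get(cluster)
    if node is None:
        return None
    leaf = TreeNode(taxon=name)
    if node is tree.root:
        return PhyloTree(leaf)
    parent = node.parent
    idx = parent.children.index(node)
    parent.children[idx] = leaf
    leaf.parent = parent
    while not tree.root.is_leaf and len(tree.root.children) == 1 \
            and not tree.root.children[0].is_leaf \
            and len(tree.root.children[0].children) == 1:
        tree.root = tree.root.children[0]
        tree.root.parent = None
    return tree


def _clusters_to_nodes(tree: PhyloTree) -> dict[frozenset, TreeNode]:
    below: dict[TreeNode, frozenset] = {}
    out: dict[frozenset, TreeNode] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset({node.taxon})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        out[below[node]] = node
    return out


def subtree_reduction(trees: Sequence[PhyloTree]
                      ) -> tuple[list[PhyloTree], dict[str, PhyloTree]]:
    """Replace maximal congruent subtrees by formal taxa.

    A taxon set qualifies when every tree containing any of its taxa
    contains all of them as a clade with the same topology.  Maximal
    qualifying sets are pairwise disjoint and are each replaced by a
    fresh formal taxon; the substitution map allows re-expansion.
    """
    if len(trees) < 2:
        return [t.copy() for t in trees], {}
    qualifying = _qualifying_common_subtrees(trees)
    maximal = [C for C in qualifying
               if not any(C < D for D in qualifying)]
    maximal.sort(key=lambda c: sorted(c))
    if not maximal:
        return [t.copy() for t in trees], {}
    union = frozenset().union(*(t.taxa() for t in trees))
    names = _fresh_names(union, len(maximal))
    substitutions: dict[str, PhyloTree] = {}
    out = [t.copy() for t in trees]
    for C, name in zip(maximal, names):
        donor = next(t for t in out if C <= t.taxa())
        node = _clusters_to_nodes(donor)[C]
        substitutions[name] = normalize_root(PhyloTree(node).copy())
        out = [_replace_clade(t, C, name) if C <= t.taxa() else t
               for t in out]
        out = [normalize_root(t) for t in out]
    return out, substitutions


def cluster_reduction(trees: Sequence[PhyloTree], min_size: int = 3
                      ) -> Optional[tuple[list[PhyloTree], list[PhyloTree], str]]:
    """Split on a common cluster into an above- and a within-problem.

    Returns ``(above_trees, within_trees, formal_taxon)`` when a proper
    taxon subset of size >= ``min_size`` is a cluster in every tree
    containing any of its members (after restriction, for partial
    trees); ``None`` otherwise.  Smaller common clusters are left to the
    subtree reduction.
    """
    if len(trees) < 2:
        return None
    union = frozenset().union(*(t.taxa() for t in trees))
    n = len(union)
    all_clusters = [t.clusters() for t in trees]
    all_taxa = [t.taxa() for t in trees]
    candidates = set()
    for clusters in all_clusters:
        candidates.update(c for c in clusters if min_size <= len(c) < n)
    common = []
    for C in sorted(candidates, key=lambda c: (-len(c), sorted(c))):
        ok = True
        for clusters, taxa in zip(all_clusters, all_taxa):
            inter = C & taxa
            if not inter:
                continue
            if len(inter) == 1:
                # a single shared member restricts to a trivial cluster
                continue
            if inter not in clusters:
                ok = False
                break
        if ok:
            common.append(C)
            break  # largest common cluster wins
    if not common:
        return None
    C = common[0]
    name = _fresh_names(union, 1, stem="C")[0]
    above: list[PhyloTree] = []
    within: list[PhyloTree] = []
    for tree in trees:
        inter = C & tree.taxa()
        if not inter:
            above.append(tree.copy())
            continue
        if len(inter) >= 2:
            within.append(restrict(tree, inter))
        if inter == tree.taxa():
            above.append(normalize_root(PhyloTree(TreeNode(taxon=name))))
        elif len(inter) == 1:
            # relabel the single shared leaf as the formal taxon
            t = tree.copy()
            t.leaf_map()[next(iter(inter))].taxon = name
            above.append(t)
        else:
            t = _replace_clade(tree.copy(), inter, name)
            above.append(normalize_root(t))
    return above, within, name


# ----------------------------------------------------------------------
# network grafting


def _graft_network(net: PhyloNetwork, formal: str,
                   sub: PhyloNetwork) -> PhyloNetwork:
    """Replace the leaf labelled ``formal`` by the network ``sub``."""
    import networkx as nx

    G = nx.MultiDiGraph()
    for v, data in net.graph.nodes(data=True):
        G.add_node(("a", v), **data)
    for u, v, k in net.graph.edges(keys=True):
        G.add_edge(("a", u), ("a", v))
    target = None
    for v in net.leaves():
        if net.taxon_of(v) == formal:
            target = ("a", v)
            break
    if target is None:
        raise TreeValidationError(f"formal taxon {formal!r} not in network")
    entry = sub.root
    succ = list(sub.graph.successors(entry))
    if sub.graph.out_degree(entry) == 1:
        entry = succ[0]  # skip the unary root node
    for v, data in sub.graph.nodes(data=True):
        G.add_node(("b", v), **data)
    for u, v, k in sub.graph.edges(keys=True):
        G.add_edge(("b", u), ("b", v))
    for p, _, k in list(G.in_edges(target, keys=True)):
        G.add_edge(p, ("b", entry))
        G.remove_edge(p, target, k)
    G.remove_node(target)
    # drop unreachable bits of sub's old root chain
    root = ("a", net.root)
    reachable = {root} | set(nx.descendants(G, root))
    G.remove_nodes_from([v for v in list(G) if v not in reachable])
    out = PhyloNetwork(G, root)
    return out


def _network_from_tree(tree: PhyloTree) -> PhyloNetwork:
    return PhyloNetwork.from_tree(normalize_root(tree))


# ----------------------------------------------------------------------
# recursive driver


def fuse(trees: Sequence[PhyloTree],
         config: Optional[FusionConfig] = None) -> FusionResult:
    """Fuse rooted trees into a tree-child network displaying them all.

    Runs preprocessing (mutual refinement, removal of displayed trees),
    factors out common subtrees and clusters, searches taxon orderings
    greedily on each reduced subproblem, and re-expands the formal taxa.
    """
    if not trees:
        raise TreeValidationError("fuse requires at least one input tree")
    if config is None:
        config = FusionConfig()
    prepared = []
    for t in trees:
        t = t.copy()
        t.validate()
        if config.support_threshold is not None:
            t = contract_low_support(t, config.support_threshold)
        prepared.append(normalize_root(t))
    deadline = time.monotonic() + config.timeout
    stats: list[FusionResult] = []
    network = _fuse_rec(prepared, config, deadline, stats)
    from .netcheck import hybridization_number

    h = hybridization_number(network)
    if len(stats) == 1:
        ordering, rounds_used = stats[0].ordering, stats[0].rounds_used
    else:
        union = sorted(set().union(*(t.taxa() for t in prepared)))
        ordering = TaxonOrdering(union)
        rounds_used = sum(s.rounds_used for s in stats)
    return FusionResult(network, h, ordering, rounds_used)


def _fuse_rec(trees: list[PhyloTree], config: FusionConfig,
              deadline: float, stats: list) -> PhyloNetwork:
    remaining = max(deadline - time.monotonic(), 1.0)
    local = replace(config, timeout=remaining)
    if len(trees) > 1:
        trees = softheur.mutual_refine(trees)
        trees = softheur.drop_displayed_subtrees(trees)
    if len(trees) == 1:
        return _network_from_tree(trees[0])
    reduced, substitutions = subtree_reduction(trees)
    reduced = [t for t in reduced]
    split = cluster_reduction(reduced) if config.cluster_reduction else None
    if split is not None:
        above, within, formal = split
        logger.debug("cluster reduction on %d taxa as %s",
                     len(within[0].taxa()) if within else 0, formal)
        net_above = _fuse_rec(above, config, deadline, stats)
        net_within = _fuse_rec(within, config, deadline, stats)
        network = _graft_network(net_above, formal, net_within)
    else:
        result = greedy_ordering_search(reduced, local)
        stats.append(result)
        network = result.network
    for formal, subtree in substitutions.items():
        network = _graft_network(network, formal,
                                 _network_from_tree(subtree))
    return network
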