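"""Verification and scoring of rooted phylogenetic networks.

Hybridization number, the tree-child test, hard/soft display of a tree in
a network, isomorphism checks, and an exhaustive optimality oracle for
tiny instances.  Display is decided by enumerating reticulation
resolutions (one retained in-edge per reticulate node), restricting the
resolved tree to the input tree's taxa and comparing cluster sets: hard
display demands cluster-set equality (multifurcations preserved exactly),
soft display only demands that the resolved tree refine the input
(cluster-set containment), which is sound and complete because edge
contraction removes clusters and never adds any.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from .encoding import TaxonOrdering, encode_lth
from .treeio import PhyloNetwork, PhyloTree, TreeValidationError, normalize_root

__all__ = [
    "DisplayWitness",
    "DisplayResult",
    "ResolutionLimitError",
    "hybridization_number",
    "is_tree_child",
    "isomorphic_trees",
    "isomorphic_networks",
    "displays_hard",
    "displays_soft",
    "brute_force_min_h",
]

#: cap on the number of reticulation resolutions a display check will try
MAX_RESOLUTIONS = 1 << 20


class ResolutionLimitError(RuntimeError):
    """Too many reticulation resolutions to enumerate."""


def hybridization_number(network: PhyloNetwork) -> int:
    """Sum over non-root nodes of (in-degree - 1); zero iff a tree."""
    G = network.graph
    return sum(G.in_degree(v) - 1 for v in G if v != network.root)


def is_tree_child(network: PhyloNetwork) -> bool:
    """Every non-leaf node has at least one child of in-degree one."""
    G = network.graph
    for v in G:
        if G.out_degree(v) == 0:
            continue
        if not any(G.in_degree(c) == 1 for c in G.successors(v)):
            return False
    return True


def isomorphic_trees(t1: PhyloTree, t2: PhyloTree) -> bool:
    """Cluster-set equality over a common taxon set."""
    return t1.taxa() == t2.taxa() and t1.clusters() == t2.clusters()


def isomorphic_networks(n1: PhyloNetwork, n2: PhyloNetwork) -> bool:
    import networkx.algorithms.isomorphism as iso

    if n1.taxa() != n2.taxa():
        return False
    nm = iso.categorical_node_match("taxon", None)
    matcher = iso.MultiDiGraphMatcher(n1.graph, n2.graph, node_match=nm)
    return matcher.is_isomorphic()


# ----------------------------------------------------------------------
# display


@dataclass
class DisplayWitness:
    """One retained in-edge per reticulate node plus the embedded clusters."""

    retained_edges: dict
    clusters: frozenset


@dataclass
class DisplayResult:
    displayed: bool
    witness: Optional[DisplayWitness] = None

    def __bool__(self) -> bool:
        return self.displayed


def _resolution_space(network: PhyloNetwork) -> list[tuple[object, list]]:
    G = network.graph
    space = []
    for v in G:
        if G.in_degree(v) >= 2:
            space.append((v, list(G.in_edges(v, keys=True))))
    return space


def _topological(network: PhyloNetwork) -> Iterator:
    import networkx as nx

    return nx.topological_sort(network.graph)


def _display(network: PhyloNetwork, tree: PhyloTree, hard: bool,
             max_resolutions: int = MAX_RESOLUTIONS) -> DisplayResult:
    taxa = tree.taxa()
    if not taxa <= network.taxa():
        raise TreeValidationError(
            "tree taxa are not covered by the network")
    target = tree.clusters()
    space = _resolution_space(network)
    count = math.prod(len(edges) for _, edges in space) if space else 1
    if count > max_resolutions:
        raise ResolutionLimitError(
            f"{count} resolutions exceed the limit of {max_resolutions}")
    order = list(_topological(network))
    G = network.graph
    # precompute static structure once; per resolution only `drop` varies
    for choice in itertools.product(*(edges for _, edges in space)):
        drop = set()
        for (_, edges), kept in zip(space, choice):
            drop.update(e for e in edges if e != kept)
        clusters = _resolved_clusters_fast(G, order, drop, taxa)
        ok = clusters == target if hard else target <= clusters
        if ok:
            retained = {v: kept for (v, _), kept in zip(space, choice)}
            return DisplayResult(True, DisplayWitness(retained, clusters))
    return DisplayResult(False, None)


def _resolved_clusters_fast(G, order: Sequence, drop: set,
                            taxa: frozenset) -> frozenset:
    below: dict = {}
    clusters = set()
    for v in reversed(order):
        if G.out_degree(v) == 0:
            taxon = G.nodes[v].get("taxon")
            acc = frozenset({taxon}) if taxon in taxa else frozenset()
        else:
            acc = frozenset()
            for _, c, k in G.out_edges(v, keys=True):
                if (v, c, k) not in drop:
                    acc = acc | below[c]
        below[v] = acc
        if acc:
            clusters.add(acc)
    return frozenset(clusters)


def displays_hard(network: PhyloNetwork, tree: PhyloTree,
                  max_resolutions: int = MAX_RESOLUTIONS) -> DisplayResult:
    """Is some resolution, restricted to the tree's taxa, isomorphic to it?

    Multifurcations must be preserved exactly.
    """
    return _display(network, tree, hard=True, max_resolutions=max_resolutions)


def displays_soft(network: PhyloNetwork, tree: PhyloTree,
                  max_resolutions: int = MAX_RESOLUTIONS) -> DisplayResult:
    """Does some resolution, restricted to the tree's taxa, refine it?"""
    return _display(network, tree, hard=False, max_resolutions=max_resolutions)


# ----------------------------------------------------------------------
# exhaustive oracle


def _exact_scs_refs(parts: Sequence[tuple], taxon: str) -> dict[str, int]:
    """Exact shortest common super-hypersequence of one taxon's rows.

    Uniform-cost search over index vectors; each emission advances a
    nonempty subset of rows whose front elements form a containment
    chain, and costs the number of foreign taxa in the merged element.
    Minimising that cost minimises the reticulation references the row
    contributes, which is what the hybridization number counts.
    Returns the per-taxon reference counts of one optimal solution.
    """
    k = len(parts)
    start = (0,) * k
    goal = tuple(len(p) for p in parts)
    # state -> (cost, predecessor, emitted element)
    dist = {start: 0}
    prev: dict = {start: (None, None)}
    heap = [(0, start)]
    while heap:
        cost, state = heapq.heappop(heap)
        if state == goal:
            break
        if cost > dist.get(state, math.inf):
            continue
        fronts = [(i, parts[i][state[i]]) for i in range(k)
                  if state[i] < len(parts[i])]
        for r in range(1, len(fronts) + 1):
            for subset in itertools.combinations(fronts, r):
                elems = sorted((e for _, e in subset), key=len)
                if any(not (elems[i] <= elems[i + 1])
                       for i in range(len(elems) - 1)):
                    continue  # not a containment chain
                merged = elems[-1]
                step = len(merged - {taxon})
                nxt = list(state)
                for i, _ in subset:
                    nxt[i] += 1
                nxt = tuple(nxt)
                ncost = cost + step
                if ncost < dist.get(nxt, math.inf):
                    dist[nxt] = ncost
                    prev[nxt] = (state, merged)
                    heapq.heappush(heap, (ncost, nxt))
    refs: dict[str, int] = {}
    state = goal
    while prev[state][0] is not None:
        state, merged = prev[state]
        for member in merged:
            if member != taxon:
                refs[member] = refs.get(member, 0) + 1
    return refs


def brute_force_min_h(trees: Sequence[PhyloTree],
                      max_h: int = 2) -> Optional[int]:
    """Exact minimum hybridization number over all taxon orderings.

    Enumerates every ordering of the union taxon set and solves each
    per-taxon shortest common super-hypersequence problem exactly, which
    characterises the tree-child optimum.  Deliberately restricted to
    desk-scale instances (n <= 6, at most 3 trees).  Returns the minimum
    if it does not exceed ``max_h``, else ``None``.
    """
    union = sorted(set().union(*(t.taxa() for t in trees)))
    if len(union) > 6 or len(trees) > 3:
        raise ValueError("brute_force_min_h is limited to n <= 6 and <= 3 trees")
    normalized = [normalize_root(t) for t in trees]
    best = math.inf
    for perm in itertools.permutations(union):
        ordering = TaxonOrdering(perm)
        encodings = [encode_lth(t, ordering) for t in normalized]
        total_refs: dict[str, int] = {t: 0 for t in union}
        for x in union:
            parts = [e.rows[x] for e in encodings if x in e.rows]
            if not parts:
                continue
            for member, n in _exact_scs_refs(parts, x).items():
                total_refs[member] += n
        h = sum(max(total_refs[x], 1) - 1 for x in perm[1:])
        if h < best:
            best = h
            if best == 0:
                break
    return int(best) if best <= max_h else None
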