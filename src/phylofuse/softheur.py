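"""Heuristics that close the gap from hard display to soft display.

Hard display treats every multifurcation as a genuine multiway split and
every missing taxon as genuinely absent, which inflates the hybridization
number.  Two tree-level preprocessing steps (mutual refinement and removal
of trees displayed by other trees) and two encoding-level rewrites (the
refinement and add-leaf transformations) reduce that inflation while
keeping every original tree soft-displayed.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

from .encoding import LTHEncoding, TaxonOrdering
from .treeio import PhyloTree, TreeNode, restrict

logger = logging.getLogger(__name__)

__all__ = [
    "mutual_refine",
    "drop_displayed_subtrees",
    "refine_heuristic",
    "add_leaf_heuristic",
]


# ----------------------------------------------------------------------
# tree-level preprocessing


def _cluster_nodes(tree: PhyloTree) -> dict[frozenset, TreeNode]:
    below: dict[TreeNode, frozenset] = {}
    out: dict[frozenset, TreeNode] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset({node.taxon})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        out[below[node]] = node
    return out


def _try_insert_cluster(tree: PhyloTree, cluster: frozenset) -> bool:
    """Group the children of a multifurcation to create ``cluster``.

    Succeeds only when the cluster is the exact union of two or more (but
    not all) children of a single node; existing clusters are never
    destroyed.
    """
    below: dict[TreeNode, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset({node.taxon})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
    for node in tree.postorder():
        if node.is_leaf or below[node] == cluster:
            continue
        if not cluster < below[node]:
            continue
        hit = [c for c in node.children if below[c] & cluster]
        if any(not below[c] <= cluster for c in hit):
            return False  # incompatible: straddles a child
        if frozenset().union(*(below[c] for c in hit)) != cluster:
            return False
        if len(hit) < 2 or len(hit) == len(node.children):
            return False
        group = TreeNode()
        idx = node.children.index(hit[0])
        for c in hit:
            node.children.remove(c)
        node.children.insert(idx, group)
        group.parent = node
        for c in hit:
            group.add(c)
        return True
    return False


def mutual_refine(trees: Sequence[PhyloTree]) -> list[PhyloTree]:
    """Resolve multifurcations in each tree using the other trees' clusters.

    For each tree in input order, candidate clusters from the other trees
    (restricted to the tree's taxa) are tried by decreasing size; a
    candidate is inserted only when it is compatible with every existing
    cluster.  Each output tree refines its input.
    """
    out = [t.copy() for t in trees]
    all_clusters = [t.clusters() for t in trees]
    for i, tree in enumerate(out):
        taxa = tree.taxa()
        candidates: set[frozenset] = set()
        for j, clusters in enumerate(all_clusters):
            if i == j:
                continue
            for c in clusters:
                cc = c & taxa
                if 1 < len(cc) < len(taxa):
                    candidates.add(cc)
        for cluster in sorted(candidates, key=lambda c: (-len(c), sorted(c))):
            if cluster in tree.clusters():
                continue
            _try_insert_cluster(tree, cluster)
    return out


def drop_displayed_subtrees(trees: Sequence[PhyloTree]) -> list[PhyloTree]:
    """Remove trees soft-displayed by another input tree on its own.

    ``T_j`` is dropped when some other tree, restricted to ``T_j``'s taxa,
    refines it (cluster-set containment).  At least one tree remains.
    """
    keep = list(trees)
    i = 0
    while i < len(keep) and len(keep) > 1:
        tj = keep[i]
        xj = tj.taxa()
        cj = tj.clusters()
        dropped = False
        for k, ti in enumerate(keep):
            if k == i or not xj <= ti.taxa():
                continue
            if cj <= restrict(ti, xj).clusters():
                logger.debug("dropping tree %d: displayed by tree %d", i, k)
                keep.pop(i)
                dropped = True
                break
        if not dropped:
            i += 1
    return keep


# ----------------------------------------------------------------------
# encoding-level heuristics

AcceptFn = Callable[[list[LTHEncoding]], bool]


def _occurrences(row, member) -> int:
    return sum(1 for element in row if member in element)


def refine_heuristic(encodings: Sequence[LTHEncoding],
                     accept: Optional[AcceptFn] = None) -> list[LTHEncoding]:
    """Resolve multifurcation elements toward a taxon seen elsewhere.

    For a multi-taxon element ``E`` in the row of ``x`` in tree ``i``,
    pick ``y in E`` and ``R subset of E - {y}`` such that no member of
    ``R`` occurs anywhere else in ``x``'s row in any tree, and some other
    tree ``j`` has ``y`` in its row of ``x`` and all of ``R`` in its row
    of ``y``; then delete ``R`` from ``E`` and insert ``R`` right after
    the head of tree ``i``'s row of ``y``.  The largest ``R`` wins, ties
    broken by the smallest ``y``.  Applied to a fixpoint; an ``accept``
    callback may veto individual rewrites (used by the fusion driver to
    keep only rewrites that do not increase the hybridization number).
    """
    encs = [e.copy() for e in encodings]
    if not encs:
        return encs
    ordering = encs[0].ordering
    vetoed: set = set()
    changed = True
    guard = 0
    while changed and guard < 10_000:
        changed = False
        guard += 1
        application = _find_refinement(encs, ordering, vetoed)
        if application is None:
            break
        i, x, pos, y, R, j = application
        candidate = [e.copy() for e in encs]
        row = list(candidate[i].rows[x])
        element = row[pos] - R
        row[pos] = element
        candidate[i].rows[x] = tuple(row)
        yrow = list(candidate[i].rows[y])
        yrow.insert(1, frozenset(R))
        candidate[i].rows[y] = tuple(yrow)
        if accept is None or accept(candidate):
            encs = candidate
            changed = True
            logger.debug("refine: tree %d, row %s, E->%s via y=%s R=%s",
                         i, x, set(element), y, set(R))
        else:
            vetoed.add((i, x, pos, y, frozenset(R)))
    return encs


def _find_refinement(encs, ordering: TaxonOrdering, vetoed):
    best = None
    for i, enc in enumerate(encs):
        for x, row in enc.rows.items():
            for pos, element in enumerate(row):
                if len(element) < 2:
                    continue
                # members of E that occur nowhere else in x's row, any tree
                free = set()
                for member in element:
                    if member == x:
                        continue
                    occ = 0
                    for e2 in encs:
                        if x in e2.rows:
                            r2 = e2.rows[x]
                            occ += sum(1 for p2, el in enumerate(r2)
                                       if member in el
                                       and not (e2 is enc and p2 == pos))
                    if occ == 0:
                        free.add(member)
                for y in ordering.sorted(element):
                    if y == x:
                        continue
                    for j, other in enumerate(encs):
                        if j == i or x not in other.rows or y not in other.rows:
                            continue
                        if not any(y in el for el in other.rows[x]):
                            continue
                        members_j = set().union(*other.rows[y])
                        R = frozenset((free - {y}) & members_j)
                        if not R or (i, x, pos, y, R) in vetoed:
                            continue
                        cand = (i, x, pos, y, R, j)
                        if best is None or (-len(R), ordering.key(y)) < \
                                (-len(best[4]), ordering.key(best[3])):
                            best = cand
    return best


def add_leaf_heuristic(encodings: Sequence[LTHEncoding],
                       accept: Optional[AcceptFn] = None
                       ) -> list[LTHEncoding]:
    """Graft a missing taxon into a tree at the encoding level.

    If taxon ``x`` is in tree ``i`` but not tree ``j``, occurs in tree
    ``i``'s row of some ``w < x``, and some ``y > x`` occurs both in tree
    ``j``'s row of ``w`` and in tree ``i``'s row of ``x``, then ``y`` is
    replaced by ``x`` in tree ``j``'s row of ``w`` and tree ``j`` gains
    the row ``x: (x, y, x)``.  Smallest ``w`` then smallest ``y`` wins.
    """
    encs = [e.copy() for e in encodings]
    if not encs:
        return encs
    ordering = encs[0].ordering
    vetoed: set = set()
    guard = 0
    while guard < 10_000:
        guard += 1
        application = _find_add_leaf(encs, ordering, vetoed)
        if application is None:
            break
        i, j, x, w, y, pos = application
        candidate = [e.copy() for e in encs]
        row = list(candidate[j].rows[w])
        row[pos] = (row[pos] - {y}) | {x}
        candidate[j].rows[w] = tuple(row)
        newrows = dict(candidate[j].rows)
        newrows[x] = (frozenset({x}), frozenset({y}), frozenset({x}))
        candidate[j] = LTHEncoding(ordering, newrows)
        if accept is None or accept(candidate):
            encs = candidate
            logger.debug("add-leaf: taxon %s added to tree %d via w=%s y=%s",
                         x, j, w, y)
        else:
            vetoed.add((i, j, x, w, y))
    return encs


def _find_add_leaf(encs, ordering: TaxonOrdering, vetoed):
    key = ordering.key
    for j, encj in enumerate(encs):
        missing = [x for x in ordering.taxa if x not in encj.rows]
        for x in missing:
            for i, enci in enumerate(encs):
                if i == j or x not in enci.rows:
                    continue
                xrow_members = set().union(*enci.rows[x])
                for w in sorted(encj.rows, key=key):
                    if key(w) >= key(x) or w not in enci.rows:
                        continue
                    if not any(x in el for el in enci.rows[w]):
                        continue
                    wrow_j = encj.rows[w]
                    ys = sorted(
                        {y for el in wrow_j for y in el
                         if key(y) > key(x) and y in xrow_members},
                        key=key)
                    for y in ys:
                        if (i, j, x, w, y) in vetoed:
                            continue
                        pos = next(p for p, el in enumerate(wrow_j)
                                   if y in el)
                        return i, j, x, w, y, pos
    return None
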