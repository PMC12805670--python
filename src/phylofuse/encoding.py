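"""Lineage-taxon-hypersequence (LTH) encoding and decoding of rooted trees.

Under a fixed total ordering of the taxa, every node of a (root-normalised)
tree receives a label: the root is labelled by the smallest taxon of the
tree, each leaf by its own taxon, each bifurcating node by the larger of
the smallest taxa below its two children, and each multifurcating node by
the set of smallest taxa below its children minus the smallest of those.
Reading the labels along the path from a taxon's internal occurrence to
its leaf yields one hypersequence per taxon; elements are singletons
except where multifurcations contribute sets.  For bifurcating trees this
specialises to the all-singleton LTS encoding.

Decoding maps every element to a node, chains consecutive elements of a
row, joins every element containing a foreign taxon ``y`` to the head of
``y``'s row, and suppresses through nodes.  A single tree's encoding
decodes back to the tree; a merged encoding decodes to a network whose
reticulations sit at row heads, which makes the result tree-child.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx

from .treeio import PhyloNetwork, PhyloTree, TreeNode, TreeValidationError

__all__ = [
    "HyperElement",
    "Hypersequence",
    "TaxonOrdering",
    "LTHEncoding",
    "DecodabilityError",
    "lambda_label",
    "encode_lth",
    "decode",
    "reference_counts",
    "encoding_h",
    "format_encoding",
]

HyperElement = frozenset  # of taxon names
Hypersequence = tuple  # of HyperElement


class DecodabilityError(ValueError):
    """An encoding cannot be decoded: some taxon is never referenced."""

    def __init__(self, taxon: str):
        self.taxon = taxon
        super().__init__(
            f"taxon {taxon!r} is not referenced by any other row; "
            "the encoding is not decodable")


class TaxonOrdering:
    """A total order on the union taxon set, mapping each taxon to a rank."""

    __slots__ = ("taxa", "rank")

    def __init__(self, taxa: Sequence[str]):
        self.taxa: tuple[str, ...] = tuple(taxa)
        self.rank: dict[str, int] = {t: i for i, t in enumerate(self.taxa)}
        if len(self.rank) != len(self.taxa):
            raise TreeValidationError("ordering contains duplicate taxa")

    @classmethod
    def lexicographic(cls, taxa: Iterable[str]) -> "TaxonOrdering":
        return cls(sorted(set(taxa)))

    def key(self, taxon: str) -> int:
        return self.rank[taxon]

    def min_of(self, taxa: Iterable[str]) -> str:
        return min(taxa, key=self.rank.__getitem__)

    def sorted(self, taxa: Iterable[str]) -> list[str]:
        return sorted(taxa, key=self.rank.__getitem__)

    def __len__(self) -> int:
        return len(self.taxa)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonOrdering) and self.taxa == other.taxa

    def __hash__(self) -> int:
        return hash(self.taxa)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonOrdering({'<'.join(self.taxa)})"


class LTHEncoding:
    """Ordered map taxon -> hypersequence under a fixed taxon ordering.

    Per-tree encodings contain rows only for the taxa present in that
    tree; a merged (SCH) encoding covers the whole taxon set.  Rows are
    kept in ordering-rank order.
    """

    __slots__ = ("ordering", "rows")

    def __init__(self, ordering: TaxonOrdering,
                 rows: Mapping[str, Hypersequence]):
        self.ordering = ordering
        self.rows: dict[str, Hypersequence] = {
            t: tuple(rows[t]) for t in ordering.sorted(rows)}

    def taxa(self) -> list[str]:
        return list(self.rows)

    def copy(self) -> "LTHEncoding":
        return LTHEncoding(self.ordering, dict(self.rows))

    def __eq__(self, other) -> bool:
        return (isinstance(other, LTHEncoding)
                and self.ordering == other.ordering
                and self.rows == other.rows)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LTHEncoding({format_encoding(self)!r})"


def _format_element(element: HyperElement, ordering: TaxonOrdering) -> str:
    if len(element) == 1:
        return next(iter(element))
    return "{" + ",".join(ordering.sorted(element)) + "}"


def format_encoding(encoding: LTHEncoding) -> str:
    """Plain-text dump, one row per line: ``x: a {b,c} e a``."""
    lines = []
    for taxon, row in encoding.rows.items():
        parts = " ".join(_format_element(e, encoding.ordering) for e in row)
        lines.append(f"{taxon}: {parts}")
    return "\n".join(lines)


# ----------------------------------------------------------------------


def lambda_label(tree: PhyloTree,
                 ordering: TaxonOrdering) -> dict[TreeNode, HyperElement]:
    """Node labelling that underlies the LTH encoding.

    Requires a root-normalised tree (root out-degree one) whose taxa are
    all covered by ``ordering``.
    """
    root = tree.root
    if root.is_leaf or len(root.children) != 1:
        raise TreeValidationError(
            "lambda labelling requires a root of out-degree one")
    rank = ordering.rank
    minbelow: dict[TreeNode, str] = {}
    labels: dict[TreeNode, HyperElement] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.taxon not in rank:
                raise TreeValidationError(
                    f"taxon {node.taxon!r} missing from the ordering")
            minbelow[node] = node.taxon
            labels[node] = frozenset({node.taxon})
        else:
            mins = [minbelow[c] for c in node.children]
            minbelow[node] = min(mins, key=rank.__getitem__)
            if node is root:
                labels[node] = frozenset({minbelow[node]})
            elif len(mins) == 2:
                labels[node] = frozenset({max(mins, key=rank.__getitem__)})
            else:
                labels[node] = frozenset(mins) - {minbelow[node]}
    return labels


def encode_lth(tree: PhyloTree, ordering: TaxonOrdering) -> LTHEncoding:
    """Extract the per-taxon hypersequences of a tree.

    The row of taxon ``x`` runs from its internal occurrence down to its
    leaf; when the internal occurrence sits inside a multifurcation label
    the row starts with the singleton ``{x}`` instead of the full set.
    For a bifurcating full tree the result is the all-singleton LTS
    encoding.
    """
    labels = lambda_label(tree, ordering)
    rows: dict[str, Hypersequence] = {}
    for taxon, leaf in tree.leaf_map().items():
        single = frozenset({taxon})
        rev: list[HyperElement] = [single]
        node = leaf.parent
        while True:
            lab = labels[node]
            if taxon in lab:
                # the internal occurrence: a singleton label for root or
                # bifurcation, or membership in a multifurcation set; the
                # row head is the singleton {x} in either case
                rev.append(single)
                break
            rev.append(lab)
            node = node.parent
        rows[taxon] = tuple(reversed(rev))
    return LTHEncoding(ordering, rows)


# ----------------------------------------------------------------------


def reference_counts(rows: Mapping[str, Hypersequence]) -> dict[str, int]:
    """Number of times each taxon occurs in rows other than its own."""
    refs: dict[str, int] = {t: 0 for t in rows}
    for taxon, row in rows.items():
        for element in row:
            for member in element:
                if member != taxon:
                    refs[member] = refs.get(member, 0) + 1
    return refs


def encoding_h(encoding: LTHEncoding) -> int:
    """Hybridization number of the decoded network, computed directly.

    Equals the sum over non-minimal taxa of (reference count - 1); a
    single tree's encoding therefore scores 0.
    """
    taxa = encoding.taxa()
    refs = reference_counts(encoding.rows)
    h = 0
    for x in taxa[1:]:
        if refs[x] == 0:
            raise DecodabilityError(x)
        h += refs[x] - 1
    return h


def decode(encoding: LTHEncoding) -> PhyloNetwork:
    """Decode an LTH or SCH encoding into a rooted network.

    Raises :class:`DecodabilityError` when a non-minimal taxon is never
    referenced; repair of such encodings is the caller's responsibility.
    """
    rows = encoding.rows
    if not rows:
        raise TreeValidationError("cannot decode an empty encoding")
    taxa = list(rows)
    for taxon, row in rows.items():
        if not row or taxon not in row[0] or taxon not in row[-1]:
            raise TreeValidationError(
                f"row of {taxon!r} must begin and end with an element "
                "containing the taxon")
    refs = reference_counts(rows)
    for x in taxa[1:]:
        if refs[x] == 0:
            raise DecodabilityError(x)

    G = nx.MultiDiGraph()
    head = {taxon: (taxon, 0) for taxon in rows}
    for taxon, row in rows.items():
        for i in range(len(row)):
            G.add_node((taxon, i))
        for i in range(len(row) - 1):
            G.add_edge((taxon, i), (taxon, i + 1))
        G.nodes[(taxon, len(row) - 1)]["taxon"] = taxon
    for taxon, row in rows.items():
        for i, element in enumerate(row):
            for member in element:
                if member != taxon:
                    G.add_edge((taxon, i), head[member])

    root = head[taxa[0]]
    _suppress_through_nodes(G, root)
    return PhyloNetwork(G, root)


def _suppress_through_nodes(G: nx.MultiDiGraph, root) -> None:
    queue = [v for v in G if v != root
             and G.in_degree(v) == 1 and G.out_degree(v) == 1]
    for v in queue:
        if v not in G:
            continue
        if G.in_degree(v) != 1 or G.out_degree(v) != 1:
            continue
        (p, _, _), = G.in_edges(v, keys=True)
        (_, c, _), = G.out_edges(v, keys=True)
        G.remove_node(v)
        G.add_edge(p, c)
        # splicing cannot create new unary nodes: p keeps its degrees,
        # and c keeps its in-degree
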