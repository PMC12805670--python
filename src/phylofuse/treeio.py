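"""Rooted phylogenetic trees and networks, with Newick / extended-Newick I/O.

Trees are stored with children in a stable order, so every traversal is
reproducible.  Branch lengths and support values are carried through I/O
but the fusion algorithms themselves are purely topological.
"""

from __future__ import annotations

import itertools
import logging
import re
from typing import Iterable, Iterator, Optional

import dendropy
import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "TreeNode",
    "PhyloTree",
    "PhyloNetwork",
    "read_newick",
    "write_newick",
    "read_enewick",
    "write_enewick",
    "normalize_root",
    "contract_low_support",
    "restrict",
]


class NewickParseError(ValueError):
    """Malformed Newick or extended-Newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid tree or network."""


_NEWICK_META = re.compile(r"[\s(),:;\[\]']")


def _quote_label(name: str) -> str:
    if _NEWICK_META.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


class TreeNode:
    """A node of a rooted tree; leaves carry a taxon name."""

    __slots__ = ("children", "parent", "taxon", "support", "length")

    def __init__(self, taxon: Optional[str] = None,
                 support: Optional[float] = None,
                 length: Optional[float] = None):
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None
        self.taxon = taxon
        self.support = support
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "TreeNode":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.taxon!r})" if self.is_leaf else \
            f"TreeNode(<{len(self.children)} children>)"


class PhyloTree:
    """Rooted, possibly multifurcating, leaf-labelled phylogenetic tree."""

    def __init__(self, root: TreeNode):
        self.root = root

    # ------------------------------------------------------------------
    # traversal

    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_map(self) -> dict[str, TreeNode]:
        return {n.taxon: n for n in self.leaves()}

    def taxa(self) -> frozenset[str]:
        return frozenset(n.taxon for n in self.leaves())

    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    # ------------------------------------------------------------------
    # structure

    def clusters(self) -> frozenset[frozenset[str]]:
        """Set of leaf-label clusters, one per node (deduplicated).

        Two trees on the same taxon set are isomorphic iff their cluster
        sets are equal; this also holds for multifurcating trees.
        """
        below: dict[TreeNode, frozenset[str]] = {}
        out = set()
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset({node.taxon})
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            out.add(below[node])
        return frozenset(out)

    def copy(self) -> "PhyloTree":
        mapping: dict[TreeNode, TreeNode] = {}
        for node in self.postorder():
            clone = TreeNode(node.taxon, node.support, node.length)
            for child in node.children:
                clone.add(mapping[child])
            mapping[node] = clone
        return PhyloTree(mapping[self.root])

    def suppress_unary(self) -> None:
        """Remove internal non-root nodes of out-degree one (in place)."""
        for node in list(self.postorder()):
            if node is self.root or node.is_leaf:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                parent = node.parent
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if not node.taxon:
                    raise TreeValidationError("leaf without a taxon label")
                if node.taxon in seen:
                    raise TreeValidationError(
                        f"duplicate leaf label {node.taxon!r}")
                seen.add(node.taxon)
            else:
                if node is not self.root and len(node.children) < 2:
                    raise TreeValidationError(
                        "internal non-root node with out-degree < 2")

    # ------------------------------------------------------------------
    # serialisation

    def to_newick(self, lengths: bool = False, supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = _quote_label(node.taxon)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if supports and node.support is not None:
                    sup = node.support
                    s += format(sup, "g")
            if lengths and node.length is not None:
                s += ":" + format(node.length, "g")
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick()})"


# ----------------------------------------------------------------------
# Newick reading / writing (plain trees)


def _from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    mapping: dict = {}
    for dnode in dtree.postorder_node_iter():
        node = TreeNode()
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node.taxon = label
        else:
            label = dnode.label
            if label is not None:
                try:
                    val = float(label)
                except ValueError:
                    logger.warning("ignoring non-numeric internal label %r", label)
                else:
                    if 0.0 <= val <= 100.0:
                        node.support = val
                    else:
                        logger.warning(
                            "ignoring internal label %r outside [0, 100]", label)
        node.length = dnode.edge.length
        for dchild in dnode.child_nodes():
            node.add(mapping[dchild])
        mapping[dnode] = node
    tree = PhyloTree(mapping[dtree.seed_node])
    tree.suppress_unary()
    tree.validate()
    return tree


def read_newick(text: str) -> list[PhyloTree]:
    """Parse one or more semicolon-terminated Newick strings.

    Numeric internal node labels in [0, 100] are interpreted as support
    values on the edge above the node.  Duplicate leaf labels within a
    single tree are rejected.
    """
    try:
        tl = dendropy.TreeList.get(
            data=text, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except TreeValidationError:
        raise
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if not tl:
        raise NewickParseError("no trees found in input")
    return [_from_dendropy(t) for t in tl]


def write_newick(trees: Iterable[PhyloTree] | PhyloTree,
                 lengths: bool = False, supports: bool = True) -> str:
    if isinstance(trees, PhyloTree):
        trees = [trees]
    return "\n".join(t.to_newick(lengths=lengths, supports=supports)
                     for t in trees) + "\n"


# ----------------------------------------------------------------------
# elementary tree surgery


def normalize_root(tree: PhyloTree) -> PhyloTree:
    """Return a copy whose root has out-degree one.

    A new root is placed above the original root when necessary; single
    leaves also receive a root above them.  Idempotent.
    """
    out = tree.copy()
    if out.root.is_leaf or len(out.root.children) != 1:
        new_root = TreeNode()
        new_root.add(out.root)
        out.root = new_root
    return out


def contract_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract internal edges with support strictly below ``threshold``.

    ``threshold`` is a percentage in [0, 100].  Supports stored as
    fractions (<= 1.0) are rescaled to percent before comparison.  Leaf
    edges are never contracted; resulting multifurcations are retained.
    """
    if not (0.0 <= threshold <= 100.0):
        raise TreeValidationError("support threshold must be in [0, 100]")
    out = tree.copy()
    for node in list(out.postorder()):
        if node.is_leaf or node is out.root or node.parent is None:
            continue
        if node.support is None:
            continue
        sup = node.support * 100.0 if node.support <= 1.0 else node.support
        if sup < threshold:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx:idx + 1] = node.children
            for child in node.children:
                child.parent = parent
    return out


def restrict(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Rooted subtree induced by ``taxa``.

    Leaves outside ``taxa`` are deleted, through nodes suppressed and the
    root re-normalised to out-degree one.
    """
    keep = frozenset(taxa) & tree.taxa()
    if not keep:
        raise TreeValidationError("restriction to an empty taxon set")
    out = tree.copy()
    # delete unwanted leaves and prune dead branches bottom-up
    for node in list(out.postorder()):
        if node.is_leaf and node.taxon not in keep and node.parent is not None:
            node.detach()
        elif not node.is_leaf and not node.children and node.parent is not None:
            node.detach()
    # the root itself may have become childless only if keep were empty
    out.suppress_unary()
    while not out.root.is_leaf and len(out.root.children) == 1 \
            and not out.root.children[0].is_leaf:
        out.root = out.root.children[0]
        out.root.parent = None
    return normalize_root(out)


# ----------------------------------------------------------------------
# rooted phylogenetic networks


class PhyloNetwork:
    """Rooted DAG with taxon-labelled leaves, backed by a MultiDiGraph.

    An edge is a reticulation edge iff its head has in-degree >= 2.
    """

    def __init__(self, graph: nx.MultiDiGraph, root):
        self.graph = graph
        self.root = root
        self.validate()

    def validate(self) -> None:
        G = self.graph
        if self.root not in G:
            raise TreeValidationError("root not in graph")
        roots = [v for v in G if G.in_degree(v) == 0]
        if roots != [self.root] and set(roots) != {self.root}:
            raise TreeValidationError(
                f"expected a single in-degree-0 node, found {len(roots)}")
        if not nx.is_directed_acyclic_graph(G):
            raise TreeValidationError("network contains a directed cycle")
        taxa = [G.nodes[v].get("taxon") for v in G if G.out_degree(v) == 0]
        if any(t is None for t in taxa):
            raise TreeValidationError("leaf without a taxon label")
        if len(set(taxa)) != len(taxa):
            raise TreeValidationError("duplicate leaf labels in network")

    # ------------------------------------------------------------------

    def leaves(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    def taxon_of(self, v) -> Optional[str]:
        return self.graph.nodes[v].get("taxon")

    def taxa(self) -> frozenset[str]:
        return frozenset(self.taxon_of(v) for v in self.leaves())

    def reticulations(self) -> list:
        return [v for v in self.graph if self.graph.in_degree(v) >= 2]

    def is_tree(self) -> bool:
        return not self.reticulations()

    def copy(self) -> "PhyloNetwork":
        return PhyloNetwork(self.graph.copy(), self.root)

    @classmethod
    def from_tree(cls, tree: PhyloTree) -> "PhyloNetwork":
        G = nx.MultiDiGraph()
        counter = itertools.count()
        ids: dict[TreeNode, int] = {}
        for node in tree.postorder():
            v = next(counter)
            ids[node] = v
            if node.is_leaf:
                G.add_node(v, taxon=node.taxon)
            else:
                G.add_node(v)
            for child in node.children:
                G.add_edge(v, ids[child])
        return cls(G, ids[tree.root])

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PhyloNetwork({self.graph.number_of_nodes()} nodes, "
                f"{len(self.reticulations())} reticulations)")

    def to_dot(self) -> str:
        """DOT export for visual debugging."""
        lines = ["digraph N {"]
        for v in self.graph:
            taxon = self.taxon_of(v)
            label = taxon if taxon else ""
            shape = "box" if self.graph.in_degree(v) >= 2 else "ellipse"
            lines.append(f'  n{v} [label="{label}", shape={shape}];')
        for u, v, _ in self.graph.edges(keys=True):
            lines.append(f"  n{u} -> n{v};")
        lines.append("}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# extended Newick


def write_enewick(network: PhyloNetwork) -> str:
    """Serialise a network in extended Newick.

    Each reticulate node is written once in full and elsewhere as a
    ``#Hk`` stub; tree-only networks come out as plain Newick.
    """
    G = network.graph
    hid: dict = {}
    expanded: set = set()

    def visit(v) -> str:
        reticulate = G.in_degree(v) >= 2
        if reticulate and v not in hid:
            hid[v] = len(hid) + 1
        taxon = network.taxon_of(v)
        label = _quote_label(taxon) if taxon else ""
        if reticulate:
            label += f"#H{hid[v]}"
        if reticulate and v in expanded:
            return label
        expanded.add(v)
        kids = list(G.successors(v))
        # honour parallel edges: a child reached twice appears twice
        parts = []
        for u in G.successors(v):
            for _ in range(G.number_of_edges(v, u)):
                parts.append(u)
        if not parts:
            return label
        return "(" + ",".join(visit(u) for u in parts) + ")" + label

    return visit(network.root) + ";"


_TOKEN = re.compile(r"\s*([(),;]|'(?:[^']|'')*'|[^\s(),;:\[\]']+|:[-+0-9.Ee]+)")


def read_enewick(text: str) -> PhyloNetwork:
    """Parse a single extended-Newick statement into a network.

    ``#Hk`` tags identify reticulate nodes; the occurrence carrying
    children is the definition, all others are stubs that get merged.
    Plain Newick (no tags) yields a tree-shaped network.
    """
    pos = 0
    tokens: list[str] = []
    stripped = text.strip()
    while pos < len(stripped):
        m = _TOKEN.match(stripped, pos)
        if not m:
            raise NewickParseError(f"unexpected character at position {pos}")
        tokens.append(m.group(1))
        pos = m.end()

    G = nx.MultiDiGraph()
    counter = itertools.count()
    hybrids: dict[str, int] = {}  # tag -> canonical node id
    idx = 0

    def error(msg: str):
        raise NewickParseError(f"{msg} (token {idx})")

    def parse_label(v):
        nonlocal idx
        label = None
        if idx < len(tokens) and tokens[idx] not in "(),;" \
                and not tokens[idx].startswith(":"):
            label = tokens[idx]
            idx += 1
        if idx < len(tokens) and tokens[idx].startswith(":"):
            idx += 1  # branch length tolerated and ignored
        tag = None
        name = None
        if label:
            if label.startswith("'"):
                name = label[1:-1].replace("''", "'")
            elif "#" in label:
                name, _, tag = label.partition("#")
                name = name or None
            else:
                name = label
        return name, tag

    def merge(v, tag):
        if tag in hybrids:
            canon = hybrids[tag]
            for p, _, k in list(G.in_edges(v, keys=True)):
                G.add_edge(p, canon)
                G.remove_edge(p, v, k)
            for _, c, k in list(G.out_edges(v, keys=True)):
                G.add_edge(canon, c)
                G.remove_edge(v, c, k)
            name = G.nodes[v].get("taxon")
            if name is not None:
                G.nodes[canon]["taxon"] = name
            G.remove_node(v)
            return canon
        hybrids[tag] = v
        return v

    def parse_subtree():
        nonlocal idx
        v = next(counter)
        G.add_node(v)
        if idx < len(tokens) and tokens[idx] == "(":
            idx += 1
            while True:
                child = parse_subtree()
                G.add_edge(v, child)
                if idx >= len(tokens):
                    error("unterminated clade")
                if tokens[idx] == ",":
                    idx += 1
                    continue
                if tokens[idx] == ")":
                    idx += 1
                    break
                error(f"expected ',' or ')', got {tokens[idx]!r}")
        name, tag = parse_label(v)
        if name is not None:
            G.nodes[v]["taxon"] = name
        if tag is not None:
            v = merge(v, tag)
        return v

    root = parse_subtree()
    if idx >= len(tokens) or tokens[idx] != ";":
        error("missing terminating ';'")
    # internal nodes must not keep taxon attributes (supports etc.)
    for v in G:
        if G.out_degree(v) > 0 and "taxon" in G.nodes[v]:
            label = G.nodes[v]["taxon"]
            try:
                float(label)
            except ValueError:
                logger.warning("ignoring internal label %r", label)
            del G.nodes[v]["taxon"]
    return PhyloNetwork(G, root)
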