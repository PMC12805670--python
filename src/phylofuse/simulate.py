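"""Synthetic input generation for benchmarking the fusion heuristic.

The protocol mimics how discordant gene trees arise from a shared species
history: a large random background tree stands in for the species tree, a
seed tree is the subtree induced by a random taxon subset, and each input
tree is the seed tree perturbed by one or more random rooted
subtree-prune-and-regraft (rSPR) moves — the rearrangement whose single
application is displayable together with the original by one reticulation.
Optionally a proportion ``c`` of internal edges is contracted (simulating
low-support polytomies) and a proportion ``m`` of taxa deleted (simulating
missing data).  With ``k`` input trees each one rSPR from the seed, a
network soft-displaying all of them exists with hybridization number at
most ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import PhyloTree, TreeNode, TreeValidationError, normalize_root, restrict

__all__ = [
    "SimulationSpec",
    "make_background_tree",
    "sample_seed_tree",
    "apply_rspr",
    "degrade",
    "generate_instance",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated instance.

    ``n_background`` taxa in the background tree (default 500), ``n_taxa``
    in the seed tree, ``k_trees`` input trees, ``rspr_per_tree`` rSPR
    moves applied to each (default 1), a proportion ``contract_prop`` of
    internal edges contracted and ``missing_prop`` of taxa deleted per
    tree.
    """

    n_taxa: int
    k_trees: int
    n_background: int = 500
    rspr_per_tree: int = 1
    contract_prop: float = 0.0
    missing_prop: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.contract_prop < 1 and 0 <= self.missing_prop < 1):
            raise ValueError("c and m must lie in [0, 1)")
        if self.n_taxa > self.n_background:
            raise ValueError("n_taxa cannot exceed n_background")
        if self.k_trees < 1 or self.n_taxa < 2 or self.rspr_per_tree < 0:
            raise ValueError("invalid simulation sizes")


def _random_tree(names: list[str], rng: np.random.Generator,
                 model: str = "coalescent") -> PhyloTree:
    """Random rooted bifurcating tree by uniform random joins."""
    if model == "coalescent":
        pool = [TreeNode(taxon=name) for name in names]
        while len(pool) > 1:
            i, j = sorted(rng.choice(len(pool), size=2, replace=False))
            node = TreeNode()
            node.add(pool[i])
            node.add(pool[j])
            pool[j] = pool[-1]
            pool[i] = node
            pool.pop()
        return normalize_root(PhyloTree(pool[0]))
    if model == "yule":
        root = TreeNode(taxon=names[0])
        tree = PhyloTree(root)
        leaves = [root]
        for name in names[1:]:
            target = leaves[int(rng.integers(len(leaves)))]
            left = TreeNode(taxon=target.taxon)
            right = TreeNode(taxon=name)
            target.taxon = None
            target.add(left)
            target.add(right)
            leaves.remove(target)
            leaves.extend([left, right])
        return normalize_root(tree)
    raise ValueError(f"unknown tree model {model!r}")


def _taxon_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i).zfill(width)}" for i in range(1, n + 1)]


def make_background_tree(spec: SimulationSpec,
                         model: str = "coalescent") -> PhyloTree:
    """Random rooted bifurcating tree on ``spec.n_background`` taxa."""
    rng = np.random.default_rng(spec.seed)
    return _random_tree(_taxon_names(spec.n_background), rng, model=model)


def sample_seed_tree(background: PhyloTree, n_taxa: int,
                     seed: int) -> PhyloTree:
    """Induced subtree on a uniformly sampled taxon subset."""
    taxa = sorted(background.taxa())
    if n_taxa > len(taxa):
        raise TreeValidationError("subset larger than the background tree")
    rng = np.random.default_rng(seed)
    subset = rng.choice(taxa, size=n_taxa, replace=False)
    return restrict(background, set(subset.tolist()))


def apply_rspr(tree: PhyloTree, count: int, seed: int,
               max_tries: int = 100) -> PhyloTree:
    """Apply ``count`` random nontrivial rSPR moves.

    Each move prunes a random non-root subtree and regrafts it onto a
    random remaining edge; moves that recreate the current topology are
    resampled (bounded retries), so the advertised relation "k trees, one
    rSPR each, hence h <= k but h > 0 for a changed tree" is meaningful.
    """
    rng = np.random.default_rng(seed)
    current = normalize_root(tree)
    for _ in range(count):
        if current.n_leaves() < 3:
            raise TreeValidationError("rSPR requires at least 3 leaves")
        before = current.clusters()
        for attempt in range(max_tries):
            candidate = _one_rspr(current, rng)
            if candidate is not None and candidate.clusters() != before:
                current = candidate
                break
        else:
            raise TreeValidationError(
                "no nontrivial rSPR move found within retry budget")
    return current


def _one_rspr(tree: PhyloTree, rng: np.random.Generator):
    work = tree.copy()
    nodes = [n for n in work.postorder()
             if n.parent is not None and n.parent is not work.root]
    if not nodes:
        return None
    prune = nodes[int(rng.integers(len(nodes)))]
    parent = prune.parent
    prune.detach()
    if len(parent.children) == 1:
        # splice the now-unary attachment point
        only = parent.children[0]
        gp = parent.parent
        idx = gp.children.index(parent)
        gp.children[idx] = only
        only.parent = gp
    edges = [(n.parent, n) for n in work.postorder() if n.parent is not None]
    if not edges:
        return None
    top, bottom = edges[int(rng.integers(len(edges)))]
    joint = TreeNode()
    idx = top.children.index(bottom)
    top.children[idx] = joint
    joint.parent = top
    joint.add(bottom)
    joint.add(prune)
    return work


def degrade(tree: PhyloTree, c: float, m: float, seed: int) -> PhyloTree:
    """Contract a proportion ``c`` of internal edges, delete ``m`` of taxa.

    Edge counts are rounded; proportions are relative to internal edges
    (contracting a leaf edge is undefined) and to the current leaf count.
    """
    if not (0 <= c < 1 and 0 <= m < 1):
        raise TreeValidationError("c and m must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = normalize_root(tree)
    internal = [n for n in out.postorder()
                if not n.is_leaf and n.parent is not None
                and n.parent is not out.root]
    n_contract = round(c * len(internal))
    if n_contract:
        chosen = rng.choice(len(internal), size=n_contract, replace=False)
        for i in sorted(chosen, reverse=True):
            node = internal[int(i)]
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx:idx + 1] = node.children
            for child in node.children:
                child.parent = parent
    taxa = sorted(out.taxa())
    n_remove = round(m * len(taxa))
    if len(taxa) - n_remove < 2:
        raise TreeValidationError("degradation would leave fewer than 2 taxa")
    if n_remove:
        removed = set(rng.choice(taxa, size=n_remove, replace=False).tolist())
        out = restrict(out, set(taxa) - removed)
    return out


def generate_instance(spec: SimulationSpec) -> list[PhyloTree]:
    """Background tree -> seed tree -> k perturbed, degraded input trees.

    Fully reproducible from ``spec.seed``; all derived seeds stay below
    2**31.
    """
    rng = np.random.default_rng(spec.seed)
    sub = lambda: int(rng.integers(2 ** 31))
    background = make_background_tree(spec)
    seed_tree = sample_seed_tree(background, spec.n_taxa, sub())
    trees = []
    for _ in range(spec.k_trees):
        t = seed_tree
        if spec.rspr_per_tree:
            t = apply_rspr(t, spec.rspr_per_tree, sub())
        if spec.contract_prop or spec.missing_prop:
            t = degrade(t, spec.contract_prop, spec.missing_prop, sub())
        trees.append(t)
    return trees
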