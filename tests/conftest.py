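"""Shared helpers and fixtures for the phylofuse test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phylofuse.treeio import PhyloTree, TreeNode, normalize_root


def hseq(text: str) -> tuple:
    """Parse ``"a {b,c} e a"`` into a hypersequence of frozensets."""
    out = []
    for token in text.split():
        out.append(frozenset(token.strip("{}").split(",")))
    return tuple(out)


def random_binary_tree(names: list[str], rng: np.random.Generator) -> PhyloTree:
    """Random rooted bifurcating tree by uniform joins, root-normalised."""
    pool = [TreeNode(taxon=n) for n in names]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        node = TreeNode()
        node.add(pool[i])
        node.add(pool[j])
        pool[j] = pool[-1]
        pool[i] = node
        pool.pop()
    return normalize_root(PhyloTree(pool[0]))


def random_multifurcating_tree(names: list[str], rng: np.random.Generator,
                               contract_frac: float = 0.0) -> PhyloTree:
    """Random tree with a fraction of internal edges contracted away."""
    tree = random_binary_tree(names, rng)
    internal = [n for n in tree.postorder()
                if not n.is_leaf and n.parent is not None
                and n.parent is not tree.root]
    k = round(contract_frac * len(internal))
    if k:
        for i in sorted(rng.choice(len(internal), size=k, replace=False),
                        reverse=True):
            node = internal[int(i)]
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx:idx + 1] = node.children
            for child in node.children:
                child.parent = parent
    return tree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
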