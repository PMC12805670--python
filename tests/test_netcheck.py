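"""Network scoring, display checks, and the exhaustive optimality oracle."""

import networkx as nx
import pytest

from phylofuse.netcheck import (
    ResolutionLimitError,
    brute_force_min_h,
    displays_hard,
    displays_soft,
    hybridization_number,
    is_tree_child,
    isomorphic_networks,
    isomorphic_trees,
)
from phylofuse.treeio import (
    PhyloNetwork,
    TreeValidationError,
    normalize_root,
    read_enewick,
    read_newick,
)

CHERRY_SWAP_NET = "((((a,(c)#H1),b),#H1));"


def _net(text: str) -> PhyloNetwork:
    return read_enewick(text)


class TestScores:
    def test_tree_has_h_zero_and_is_tree_child(self):
        (t,) = read_newick("((a,b),(c,d));")
        net = PhyloNetwork.from_tree(normalize_root(t))
        assert hybridization_number(net) == 0
        assert is_tree_child(net)

    def test_single_reticulation(self):
        net = _net(CHERRY_SWAP_NET)
        assert hybridization_number(net) == 1
        assert is_tree_child(net)

    def test_parallel_edges_count_separately(self):
        G = nx.MultiDiGraph()
        G.add_node(2, taxon="a")
        G.add_node(3, taxon="b")
        G.add_edge(0, 1)
        G.add_edge(0, 1)  # parallel pair: one reticulation
        G.add_edge(1, 2)
        G.add_edge(0, 3)
        net = PhyloNetwork(G, 0)
        assert hybridization_number(net) == 1

    def test_not_tree_child(self):
        # every child of nodes 1 and 2 is reticulate
        G = nx.MultiDiGraph()
        for u, v in [(0, 1), (0, 2), (1, 3), (1, 4), (2, 3), (2, 4),
                     (3, 5), (4, 6)]:
            G.add_edge(u, v)
        G.add_node(5, taxon="a")
        G.add_node(6, taxon="b")
        net = PhyloNetwork(G, 0)
        assert not is_tree_child(net)


class TestDisplay:
    def test_network_displays_both_cherry_trees(self):
        net = _net(CHERRY_SWAP_NET)
        t1, t2 = read_newick("((a,b),c);\n((a,c),b);")
        assert displays_hard(net, t1)
        assert displays_hard(net, t2)
        witness = displays_hard(net, t1).witness
        assert witness is not None and witness.clusters == t1.clusters()

    def test_non_displayed_tree(self):
        net = _net(CHERRY_SWAP_NET)
        (t,) = read_newick("((b,c),a);")
        assert not displays_hard(net, t)
        assert not displays_soft(net, t)

    def test_soft_but_not_hard_for_multifurcation(self):
        net = _net("(((a,b),c));")  # fully resolved tree as a network
        (star,) = read_newick("(a,b,c);")
        assert displays_soft(net, star)
        assert not displays_hard(net, star)

    def test_partial_tree_display(self):
        net = _net(CHERRY_SWAP_NET)
        (t,) = read_newick("(a,b);")
        assert displays_hard(net, t)

    def test_taxa_not_covered_raises(self):
        net = _net(CHERRY_SWAP_NET)
        (t,) = read_newick("((a,b),z);")
        with pytest.raises(TreeValidationError):
            displays_soft(net, t)

    def test_resolution_limit(self):
        net = _net(CHERRY_SWAP_NET)
        (t,) = read_newick("((a,b),c);")
        with pytest.raises(ResolutionLimitError):
            displays_hard(net, t, max_resolutions=1)


class TestIsomorphism:
    def test_trees(self):
        t1, t2 = read_newick("((a,b),c);\n(c,(b,a));")
        assert isomorphic_trees(t1, t2)
        t3, = read_newick("((a,c),b);")
        assert not isomorphic_trees(t1, t3)

    def test_networks(self):
        n1 = _net(CHERRY_SWAP_NET)
        n2 = _net(CHERRY_SWAP_NET)
        assert isomorphic_networks(n1, n2)
        n3 = _net("((((b,(c)#H1),a),#H1));")
        assert not isomorphic_networks(n1, n3)


class TestBruteForce:
    def test_identical_trees_need_no_reticulation(self):
        trees = read_newick("((a,b),c);\n((a,b),c);")
        assert brute_force_min_h(trees) == 0

    def test_cherry_swap_needs_one(self):
        trees = read_newick("((a,b),c);\n((a,c),b);")
        assert brute_force_min_h(trees) == 1

    def test_max_h_cutoff(self):
        trees = read_newick("(((a,b),c),d);\n(((d,c),b),a);")
        result = brute_force_min_h(trees, max_h=0)
        assert result is None

    def test_size_guard(self):
        trees = read_newick("((((((a,b),c),d),e),f),g);")
        with pytest.raises(ValueError):
            brute_force_min_h([trees[0], trees[0]])
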