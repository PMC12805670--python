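"""Newick/eNewick I/O, root normalisation, support contraction, restriction."""

import pytest

from phylofuse.treeio import (
    NewickParseError,
    PhyloNetwork,
    TreeValidationError,
    contract_low_support,
    normalize_root,
    read_enewick,
    read_newick,
    restrict,
    write_enewick,
    write_newick,
)

from conftest import random_binary_tree


class TestNewick:
    def test_parse_single_tree(self):
        (t,) = read_newick("((a,b),(c,d));")
        assert t.taxa() == frozenset("abcd")
        assert frozenset("ab") in t.clusters()

    def test_parse_multifurcation(self):
        (t,) = read_newick("(a,b,c,(d,e));")
        root_children = len(t.root.children)
        assert root_children == 4

    def test_parse_multiple_statements(self):
        trees = read_newick("((a,b),c);\n((a,c),b);\n")
        assert len(trees) == 2

    def test_underscores_preserved(self):
        (t,) = read_newick("((Homo_sapiens,Pan_paniscus),Mus_musculus);")
        assert "Homo_sapiens" in t.taxa()

    def test_internal_support_values(self):
        (t,) = read_newick("((a,b)95,(c,d)40);")
        supports = sorted(n.support for n in t.postorder()
                          if n.support is not None)
        assert supports == [40.0, 95.0]

    @pytest.mark.parametrize("bad", ["((a,b),c", "((a,b),c));", "((a,a),b);", ";"])
    def test_malformed_input_raises(self, bad):
        with pytest.raises((NewickParseError, TreeValidationError)):
            read_newick(bad)

    def test_write_read_round_trip_random(self, rng):
        names = [f"s{i}" for i in range(20)]
        for _ in range(25):
            t = random_binary_tree(names, rng)
            (back,) = read_newick(write_newick(t))
            assert back.clusters() == t.clusters()


class TestNormalizeAndContract:
    def test_normalize_root_adds_unary_root(self):
        (t,) = read_newick("((a,b),c);")
        norm = normalize_root(t)
        assert len(norm.root.children) == 1
        # idempotent
        again = normalize_root(norm)
        assert len(again.root.children) == 1
        assert again.clusters() == norm.clusters()

    def test_contract_low_support(self):
        (t,) = read_newick("(((a,b)60,c)90,d);")
        out = contract_low_support(t, 70)
        assert frozenset("ab") not in out.clusters()
        assert frozenset("abc") in out.clusters()

    def test_contract_rescales_unit_supports(self):
        # supports given in [0, 1] are interpreted as fractions
        (t,) = read_newick("(((a,b)0.6,c)0.9,d);")
        out = contract_low_support(t, 70)
        assert frozenset("ab") not in out.clusters()
        assert frozenset("abc") in out.clusters()

    def test_restrict_induces_subtree(self):
        (t,) = read_newick("(((a,b),(c,d)),e);")
        sub = restrict(t, {"a", "c", "e"})
        assert sub.taxa() == frozenset("ace")
        assert frozenset("ac") in sub.clusters()


class TestENewick:
    def test_tree_round_trip(self):
        (t,) = read_newick("((a,b),(c,d));")
        net = PhyloNetwork.from_tree(normalize_root(t))
        back = read_enewick(write_enewick(net))
        assert back.taxa() == net.taxa()
        assert back.is_tree()

    def test_reticulate_round_trip(self):
        text = "((((a,(c)#H1),b),#H1));"
        net = read_enewick(text)
        assert len(net.reticulations()) == 1
        back = read_enewick(write_enewick(net))
        from phylofuse.netcheck import isomorphic_networks
        assert isomorphic_networks(net, back)

    def test_fused_network_round_trip(self):
        from phylofuse import FusionConfig, fuse
        from phylofuse.netcheck import isomorphic_networks
        trees = read_newick("((a,b),(c,d));\n((a,c),(b,d));")
        net = fuse(trees, FusionConfig()).network
        back = read_enewick(write_enewick(net))
        assert isomorphic_networks(net, back)

    def test_network_validation(self):
        import networkx as nx
        G = nx.MultiDiGraph()
        G.add_edge(0, 1)
        G.add_edge(1, 0)
        with pytest.raises(TreeValidationError):
            PhyloNetwork(G, 0)
        G2 = nx.MultiDiGraph()
        G2.add_node(0)
        G2.add_node(1, taxon="a")
        G2.add_node(2, taxon="a")
        G2.add_edge(0, 1)
        G2.add_edge(0, 2)
        with pytest.raises(TreeValidationError):
            PhyloNetwork(G2, 0)
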