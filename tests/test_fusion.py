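"""End-to-end fusion, the ordering search, and the problem reductions."""

import pytest

from phylofuse.encoding import TaxonOrdering
from phylofuse.fusion import (
    FusionConfig,
    cluster_reduction,
    evaluate_ordering,
    fuse,
    greedy_ordering_search,
    subtree_reduction,
)
from phylofuse.netcheck import (
    brute_force_min_h,
    displays_hard,
    displays_soft,
    hybridization_number,
    is_tree_child,
)
from phylofuse.treeio import TreeValidationError, normalize_root, read_newick


class TestFuse:
    def test_identical_trees_give_the_tree(self):
        trees = read_newick("((a,b),(c,d));\n((a,b),(c,d));")
        res = fuse(trees)
        assert res.h == 0
        assert res.network.is_tree()
        assert displays_hard(res.network, trees[0])

    def test_cherry_swap_one_reticulation(self):
        trees = read_newick("((a,b),c);\n((a,c),b);")
        res = fuse(trees)
        assert res.h == 1
        assert is_tree_child(res.network)
        assert displays_hard(res.network, trees[0])
        assert displays_hard(res.network, trees[1])

    def test_partial_trees_fused(self):
        trees = read_newick("((a,b),(c,d));\n((a,c),e);")
        res = fuse(trees)
        assert res.network.taxa() == frozenset("abcde")
        assert displays_soft(res.network, trees[0])
        assert displays_soft(res.network, trees[1])

    def test_multifurcating_inputs_soft_displayed(self):
        trees = read_newick("(a,b,(c,d));\n((a,b),(c,d));\n((a,c),(b,d));")
        res = fuse(trees)
        assert is_tree_child(res.network)
        for t in trees:
            assert displays_soft(res.network, t)

    def test_support_threshold_contracts_before_fusing(self):
        trees = read_newick("(((a,b)50,c)90,d);\n(((a,c)95,b)95,d);")
        low = fuse(trees, FusionConfig(support_threshold=70))
        high = fuse(trees)
        assert low.h <= high.h

    def test_single_tree(self):
        trees = read_newick("((a,b),c);")
        res = fuse(trees)
        assert res.h == 0 and res.network.is_tree()

    def test_empty_input_rejected(self):
        with pytest.raises(TreeValidationError):
            fuse([])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FusionConfig(rounds=0)


class TestOrderingSearch:
    def test_evaluate_ordering_returns_network_and_h(self):
        trees = [normalize_root(t)
                 for t in read_newick("((a,b),c);\n((a,c),b);")]
        net, h = evaluate_ordering(trees, TaxonOrdering(list("abc")))
        assert h == hybridization_number(net)

    def test_exhaustive_matches_oracle_small(self):
        trees = read_newick("(((a,b),c),d);\n(((a,c),b),d);")
        res = greedy_ordering_search(
            [normalize_root(t) for t in trees],
            FusionConfig(exhaustive_orderings=True))
        assert res.h == brute_force_min_h(trees)

    def test_exhaustive_guard(self):
        trees = read_newick("((((((((a,b),c),d),e),f),g),h),i);")
        with pytest.raises(ValueError):
            greedy_ordering_search(
                [normalize_root(trees[0])],
                FusionConfig(exhaustive_orderings=True))

    def test_deterministic_given_seed(self):
        trees = read_newick(
            "(((a,b),(c,d)),(e,f));\n(((a,c),(b,d)),(f,e));")
        r1 = fuse(trees, FusionConfig(seed=5))
        r2 = fuse(trees, FusionConfig(seed=5))
        assert r1.h == r2.h
        assert r1.ordering == r2.ordering


class TestReductions:
    def test_subtree_reduction_replaces_common_clade(self):
        trees = read_newick(
            "(((a,b),c),(d,e));\n(((a,b),d),(c,e));")
        reduced, subs = subtree_reduction(trees)
        assert len(subs) == 1
        formal, clade = next(iter(subs.items()))
        assert clade.taxa() == frozenset("ab")
        assert all(formal in t.taxa() for t in reduced)
        assert all("a" not in t.taxa() for t in reduced)

    def test_subtree_reduction_requires_identical_topology(self):
        trees = read_newick(
            "((((a,b),c),d),e);\n((((a,c),b),d),e);")
        _, subs = subtree_reduction(trees)
        assert all(clade.taxa() != frozenset("abc") for clade in subs.values())

    def test_cluster_reduction_splits_problem(self):
        trees = read_newick(
            "(((a,b),(c,d)),(e,f));\n(((a,c),(b,d)),(f,e));")
        split = cluster_reduction(trees)
        assert split is not None
        above, within, formal = split
        assert frozenset().union(*(t.taxa() for t in within)) == frozenset("abcd")
        assert all(formal in t.taxa() for t in above)

    def test_cluster_reduction_none_without_common_cluster(self):
        trees = read_newick("((a,b),(c,d));\n((a,c),(b,d));")
        assert cluster_reduction(trees) is None

    def test_fusion_with_reductions_matches_direct_search(self):
        trees = read_newick(
            "(((a,b),(c,d)),(e,f));\n(((a,c),(b,d)),(f,e));")
        with_red = fuse(trees, FusionConfig())
        without = fuse(trees, FusionConfig(cluster_reduction=False))
        for t in trees:
            assert displays_soft(with_red.network, t)
            assert displays_soft(without.network, t)
        assert is_tree_child(with_red.network)
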