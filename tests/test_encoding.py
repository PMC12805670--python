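"""Lambda labelling, LTH encoding, and decoding back to trees."""

import pytest

from phylofuse.encoding import (
    DecodabilityError,
    LTHEncoding,
    TaxonOrdering,
    decode,
    encode_lth,
    encoding_h,
    format_encoding,
    lambda_label,
    reference_counts,
)
from phylofuse.netcheck import displays_hard, hybridization_number
from phylofuse.treeio import TreeValidationError, normalize_root, read_newick

from conftest import hseq, random_multifurcating_tree


def _encode(newick: str, order: str) -> LTHEncoding:
    (t,) = read_newick(newick)
    return encode_lth(normalize_root(t), TaxonOrdering(order.split()))


class TestLambdaLabel:
    def test_requires_normalised_root(self):
        (t,) = read_newick("((a,b),c);")
        with pytest.raises(TreeValidationError):
            lambda_label(t, TaxonOrdering(["a", "b", "c"]))

    def test_caterpillar_labels(self):
        (t,) = read_newick("(((a,b),c),d);")
        t = normalize_root(t)
        labels = lambda_label(t, TaxonOrdering(list("abcd")))
        internal = sorted(
            next(iter(lab)) for node, lab in labels.items() if not node.is_leaf)
        # root carries the minimum; each bifurcation the larger child minimum
        assert internal == ["a", "b", "c", "d"]

    def test_each_taxon_twice_in_bifurcating_tree(self):
        (t,) = read_newick("((a,(b,c)),(d,e));")
        t = normalize_root(t)
        labels = lambda_label(t, TaxonOrdering(list("abcde")))
        counts = {}
        for lab in labels.values():
            for member in lab:
                counts[member] = counts.get(member, 0) + 1
        assert counts == {x: 2 for x in "abcde"}

    def test_multifurcation_label_is_set_of_child_minima(self):
        (t,) = read_newick("(a,b,(c,d));")
        t = normalize_root(t)
        labels = lambda_label(t, TaxonOrdering(list("abcd")))
        assert frozenset({"b", "c"}) in labels.values()


class TestEncode:
    def test_star_tree_rows(self):
        enc = _encode("(a,b,c);", "a b c")
        assert enc.rows["a"] == hseq("a {b,c} a")
        assert enc.rows["b"] == hseq("b b")
        assert enc.rows["c"] == hseq("c c")

    def test_cherry_rows(self):
        enc = _encode("((a,b),c);", "a b c")
        assert enc.rows["a"] == hseq("a c b a")
        assert enc.rows["b"] == hseq("b b")
        assert enc.rows["c"] == hseq("c c")

    def test_rows_begin_and_end_with_own_taxon(self, rng):
        names = [f"s{i:02d}" for i in range(12)]
        for frac in (0.0, 0.3, 0.5):
            t = random_multifurcating_tree(names, rng, frac)
            enc = encode_lth(t, TaxonOrdering.lexicographic(names))
            for x, row in enc.rows.items():
                assert row[0] == frozenset({x})
                assert x in row[-1]

    def test_reference_counts_and_h(self):
        enc = _encode("((a,b),c);", "a b c")
        refs = reference_counts(enc.rows)
        assert refs["b"] == 1 and refs["c"] == 1
        assert encoding_h(enc) == 0

    def test_format_encoding(self):
        enc = _encode("(a,b,c);", "a b c")
        assert format_encoding(enc).splitlines()[0] == "a: a {b,c} a"


class TestDecode:
    def test_single_tree_round_trip(self):
        (t,) = read_newick("((a,(b,c)),(d,e));")
        t = normalize_root(t)
        net = decode(encode_lth(t, TaxonOrdering(list("abcde"))))
        assert hybridization_number(net) == 0
        assert displays_hard(net, t)

    def test_round_trip_preserves_multifurcations(self, rng):
        names = [f"s{i:02d}" for i in range(15)]
        for frac in (0.0, 0.25, 0.5):
            for _ in range(10):
                t = random_multifurcating_tree(names, rng, frac)
                order = list(names)
                rng.shuffle(order)
                net = decode(encode_lth(t, TaxonOrdering(order)))
                assert hybridization_number(net) == 0
                assert displays_hard(net, t)

    def test_unreferenced_taxon_raises(self):
        order = TaxonOrdering(["a", "b"])
        rows = {"a": hseq("a a"), "b": hseq("b b")}
        with pytest.raises(DecodabilityError):
            decode(LTHEncoding(order, rows))

    def test_merged_encoding_decodes_with_reticulation(self):
        order = TaxonOrdering(["a", "b", "c"])
        # b is referenced twice: one reticulation
        rows = {"a": hseq("a c b a"), "b": hseq("b b"), "c": hseq("c b c")}
        net = decode(LTHEncoding(order, rows))
        assert hybridization_number(net) == 1
        assert len(net.reticulations()) == 1
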