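"""RF and triplet metrics against brute-force oracles and dendropy."""

import dendropy
import pytest

from sylva.formats_io import parse_newick, write_newick
from sylva.tree_metrics import (
    bipartitions,
    compare_trees,
    midpoint_root,
    rf_distance,
    restrict,
    root_at_outgroup,
    triplet_distance,
)

from oracles import (
    clade_sets,
    random_binary_tree,
    rooted_triplet,
    splits_by_edge_removal,
)
import itertools


class TestBipartitions:
    def test_star_tree_empty(self):
        assert bipartitions(parse_newick("(a,b,c,d,e);")) == set()

    def test_binary_tree_count(self, rng, labels10):
        t = random_binary_tree(labels10, rng, rooted=False)
        assert len(bipartitions(t)) == len(labels10) - 3

    def test_matches_edge_removal_oracle(self, rng, labels10):
        for _ in range(30):
            n = int(rng.integers(4, 11))
            t = random_binary_tree(labels10[:n], rng, rooted=bool(rng.integers(2)))
            assert bipartitions(t) == splits_by_edge_removal(t)


class TestRfDistance:
    def test_identical_trees_zero_percent(self, rng, labels10):
        t = random_binary_tree(labels10, rng)
        assert rf_distance(t, t.copy()).rf_normalized == 0.0

    def test_split_disjoint_trees_hundred_percent(self):
        t1 = parse_newick("((a,b),(c,d),e);")
        t2 = parse_newick("((a,c),(b,e),d);")
        cmp = rf_distance(t1, t2)
        assert cmp.rf_normalized == 100.0
        assert cmp.rf_raw == 4

    def test_star_reference_one_sided_zero(self, rng, labels10):
        star = parse_newick("(" + ",".join(labels10[:6]) + ");")
        est = random_binary_tree(labels10[:6], rng, rooted=False)
        cmp = rf_distance(star, est)
        assert cmp.one_sided_rf == 0.0
        assert cmp.rf_normalized > 0.0

    def test_disjoint_leaf_sets_error(self, rng):
        t1 = random_binary_tree(list("abcd"), rng)
        t2 = random_binary_tree(list("wxyz"), rng)
        with pytest.raises(ValueError, match="share no leaves"):
            rf_distance(t1, t2)

    def test_restricts_to_shared_leaves(self, rng, labels10):
        t_small = random_binary_tree(labels10[:6], rng, rooted=False)
        t_big = random_binary_tree(labels10, rng, rooted=False)
        cmp = rf_distance(t_small, t_big)
        assert cmp.n_shared_leaves == 6

    def test_matches_symmetric_difference_oracle(self, rng, labels10):
        for _ in range(40):
            n = int(rng.integers(4, 11))
            t1 = random_binary_tree(labels10[:n], rng, rooted=False)
            t2 = random_binary_tree(labels10[:n], rng, rooted=False)
            s1 = splits_by_edge_removal(t1)
            s2 = splits_by_edge_removal(t2)
            assert rf_distance(t1, t2).rf_raw == len(s1 ^ s2)

    def test_matches_dendropy(self, rng, labels10):
        """Cross-check against an established implementation."""
        for _ in range(15):
            t1 = random_binary_tree(labels10, rng, rooted=False)
            t2 = random_binary_tree(labels10, rng, rooted=False)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                                   taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2).rf_raw == expected

    def test_metric_properties(self, rng, labels10):
        for _ in range(10):
            a = random_binary_tree(labels10, rng, rooted=False)
            b = random_binary_tree(labels10, rng, rooted=False)
            c = random_binary_tree(labels10, rng, rooted=False)
            ab = rf_distance(a, b).rf_raw
            ba = rf_distance(b, a).rf_raw
            assert ab == ba
            assert rf_distance(a, a.copy()).rf_raw == 0
            assert ab <= rf_distance(a, c).rf_raw + rf_distance(c, b).rf_raw

    def test_one_sided_numerator_bounded_by_raw(self, rng, labels10):
        for _ in range(10):
            t1 = random_binary_tree(labels10, rng, rooted=False)
            t2 = random_binary_tree(labels10, rng, rooted=False)
            cmp = rf_distance(t1, t2)
            s1 = bipartitions(t1)
            assert len(s1) * cmp.one_sided_rf / 100.0 <= cmp.rf_raw + 1e-9


class TestTripletDistance:
    def test_identical_zero(self, rng, labels10):
        t = random_binary_tree(labels10, rng, rooted=True)
        assert triplet_distance(t, t.copy()) == 0.0

    def test_single_triplet_mismatch(self):
        assert triplet_distance(
            parse_newick("((a,b),c);"), parse_newick("((a,c),b);")
        ) == 1.0

    def test_unrooted_input_rejected(self, rng, labels10):
        unrooted = random_binary_tree(labels10, rng, rooted=False)
        rooted = random_binary_tree(labels10, rng, rooted=True)
        with pytest.raises(ValueError, match="root"):
            triplet_distance(rooted, unrooted)

    def test_reference_polytomy_counts_as_agreement(self):
        ref = parse_newick("((a,b,c),d);")  # unresolved triplet abc
        est = parse_newick("(((a,b),c),d);")
        assert triplet_distance(ref, est) == 0.0
        assert triplet_distance(ref, est, penalize_extra_resolution=True) > 0.0

    def test_matches_enumeration_oracle(self, rng, labels10):
        for _ in range(30):
            n = int(rng.integers(3, 10))
            t1 = random_binary_tree(labels10[:n], rng, rooted=True)
            t2 = random_binary_tree(labels10[:n], rng, rooted=True)
            c1, c2 = clade_sets(t1), clade_sets(t2)
            mism = 0
            total = 0
            for a, b, c in itertools.combinations(sorted(labels10[:n]), 3):
                total += 1
                r = rooted_triplet(c1, a, b, c)
                e = rooted_triplet(c2, a, b, c)
                if r >= 0 and e >= 0 and r != e:
                    mism += 1
            assert triplet_distance(t1, t2) == pytest.approx(mism / total)


class TestRooting:
    def test_midpoint_on_caterpillar(self):
        t = parse_newick("(a:1,(b:1,(c:1,d:10):1):1);")
        rooted = midpoint_root(t)
        # longest path is d to a (13); midpoint falls inside d's branch
        assert rooted.rooted
        first = rooted.root.children
        sides = {frozenset(c.label for c in x.walk() if c.is_leaf) for x in first}
        assert frozenset({"d"}) in sides

    def test_outgroup_rooting(self, rng, labels10):
        t = random_binary_tree(labels10, rng, rooted=False)
        rooted = root_at_outgroup(t, "c")
        side_labels = [
            {n.label for n in c.walk() if n.is_leaf} for c in rooted.root.children
        ]
        assert {"c"} in side_labels
        with pytest.raises(ValueError, match="outgroup"):
            root_at_outgroup(t, "zz")

    def test_rooting_preserves_unrooted_topology(self, rng, labels10):
        for _ in range(10):
            t = random_binary_tree(labels10, rng, rooted=False)
            rooted = midpoint_root(t)
            assert bipartitions(rooted) == bipartitions(t)


class TestRestrictAndCompare:
    def test_restrict_drops_and_suppresses(self):
        t = parse_newick("((a:1,b:1):1,(c:1,(d:1,e:1):1):1);")
        r = restrict(t, {"a", "b", "c", "d"})
        assert sorted(r.leaf_labels()) == ["a", "b", "c", "d"]
        assert bipartitions(r) == {frozenset({"c", "d"})}

    def test_compare_trees_full_report(self, rng, labels10):
        ref = random_binary_tree(labels10, rng, rooted=True)
        est = random_binary_tree(labels10, rng, rooted=False)
        cmp = compare_trees(ref, est)
        assert cmp.triplet_error is not None
        assert 0 <= cmp.rf_normalized <= 100
        assert 0 <= cmp.triplet_error <= 1
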