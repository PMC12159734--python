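"""Quartet tallying, scoring, exact and heuristic search, annotation."""

import itertools
import math

import numpy as np
import pytest

from sylva.formats_io import Tree, canonical_newick, parse_newick
from sylva.species_tree import (
    QuartetTally,
    annotate_branches,
    exact_search,
    heuristic_search,
    quartet_score,
    tally_quartets,
)

from oracles import (
    all_splits_with_trivial,
    quartet_topology_by_splits,
    random_binary_tree,
)


def gtree(newick: str) -> Tree:
    """Gene tree where leaf 'a2' means second copy in species a."""
    return parse_newick(newick)


def species_newick(newick: str) -> Tree:
    return parse_newick(newick)


def _recount_score(candidate: Tree, gene_trees, max_samples=10**9) -> float:
    """Independent O(n^4) recount: for every 4-species subset, enumerate
    leaf combinations per gene tree and compare split-derived topologies
    against the candidate's split-derived topology."""
    cand_splits = all_splits_with_trivial(candidate)
    species = sorted(candidate.leaf_labels())
    total = 0.0
    for quad in itertools.combinations(species, 4):
        w, x, y, z = quad
        cand_topo = quartet_topology_by_splits(cand_splits, w, x, y, z)
        for gt in gene_trees:
            by_sp = {}
            for lbl in gt.leaf_labels():
                by_sp.setdefault(lbl.split("|")[0], []).append(lbl)
            if not all(sp in by_sp for sp in quad):
                continue
            gt_splits = all_splits_with_trivial(gt)
            combos = list(itertools.product(*(by_sp[sp] for sp in quad)))
            wgt = 1.0 / len(combos)
            for la, lb, lc, ld in combos:
                topo = quartet_topology_by_splits(gt_splits, la, lb, lc, ld)
                # map leaf-level pairing back to species-level topology
                if topo == cand_topo:
                    total += wgt
                elif topo == -1:
                    total += wgt / 3.0
    return total


class TestTally:
    def test_unanimous_gene_trees_give_dominant_weights(self):
        gt = gtree("((a|1,b|1),(c|1,d|1),e|1);")
        tally = tally_quartets([gt] * 5)
        for qmask, w in tally.weights.items():
            assert tally.n_genes_covering[qmask] == 5
            assert max(w) == pytest.approx(5.0)
            assert sorted(w)[:2] == [0.0, 0.0]

    def test_weights_sum_to_covering_genes(self, rng):
        trees = []
        for i in range(6):
            labels = [f"s{j}|c{k}" for j in range(5) for k in range(1 + (j + i) % 2)]
            trees.append(random_binary_tree(labels, rng, rooted=False))
        tally = tally_quartets(trees, seed=0)
        for qmask, w in tally.weights.items():
            assert w.sum() == pytest.approx(tally.n_genes_covering[qmask], abs=1e-9)

    def test_multicopy_fractional_weights_match_enumeration(self):
        # two copies of species a on opposite sides of the tree
        gt = gtree("((a|1,b|1),((a|2,c|1),d|1));")
        tally = tally_quartets([gt])
        qmask = sum(tally.bit(s) for s in "abcd")
        w = tally.weights[qmask]
        # copies: (a|1): ab|cd ; (a|2): ac|bd -> weight 1/2 each
        idx = tally.pair_index(qmask)
        assert w[idx[tally.bit("a") | tally.bit("b")]] == pytest.approx(0.5)
        assert w[idx[tally.bit("a") | tally.bit("c")]] == pytest.approx(0.5)

    def test_small_trees_contribute_nothing(self):
        tally = tally_quartets([gtree("((a|1,b|1),c|1);")])
        assert tally.weights == {}


class TestQuartetScore:
    def test_candidate_equal_to_gene_tree_scores_choose4(self):
        gt = gtree("((s0|g,s1|g),((s2|g,s3|g),(s4|g,s5|g)));")
        cand = species_newick("((s0,s1),((s2,s3),(s4,s5)));")
        tally = tally_quartets([gt])
        assert quartet_score(cand, tally) == pytest.approx(math.comb(6, 4))

    def test_score_bounded_by_genes_times_choose4(self, rng):
        trees = [
            random_binary_tree([f"s{i}|g" for i in range(6)], rng, rooted=False)
            for _ in range(5)
        ]
        tally = tally_quartets(trees)
        cand = random_binary_tree([f"s{i}" for i in range(6)], rng, rooted=False)
        assert quartet_score(cand, tally) <= 5 * math.comb(6, 4) + 1e-9

    def test_missing_species_is_error(self):
        tally = tally_quartets(
            [gtree("((a|1,b|1),(c|1,d|1));")]
        )
        with pytest.raises(ValueError, match="missing"):
            quartet_score(species_newick("((a,b),c);"), tally)

    def test_matches_independent_recount(self, rng):
        """Tally-lookup scoring equals the direct O(n^4) recount on random
        multicopy gene-tree sets, n <= 7 species."""
        for trial in range(8):
            n = int(rng.integers(5, 8))
            trees = []
            for _ in range(4):
                labels = []
                for j in range(n):
                    copies = 1 + int(rng.random() < 0.3)
                    labels += [f"s{j}|c{k}" for k in range(copies)]
                trees.append(random_binary_tree(labels, rng, rooted=False))
            tally = tally_quartets(trees, seed=trial)
            cand = random_binary_tree([f"s{j}" for j in range(n)], rng, rooted=False)
            assert quartet_score(cand, tally) == pytest.approx(
                _recount_score(cand, trees), abs=1e-9
            )


class TestSearch:
    def test_single_gene_tree_recovered(self):
        gt = gtree("((s0|g,s1|g),((s2|g,s3|g),(s4|g,s5|g)));")
        tally = tally_quartets([gt])
        best = exact_search(tally, [f"s{i}" for i in range(6)])
        from sylva.tree_metrics import rf_distance

        expected = species_newick("((s0,s1),((s2,s3),(s4,s5)));")
        assert rf_distance(expected, best).rf_raw == 0

    def test_symmetric_tally_returns_canonical_smallest(self):
        species = ["a", "b", "c", "d"]
        tally = QuartetTally(species=species)
        qmask = 0b1111
        tally.weights[qmask] = np.full(3, 1.0 / 3.0)
        tally.n_genes_covering[qmask] = 1
        t1 = exact_search(tally, species)
        t2 = exact_search(tally, list(reversed(species)))
        assert canonical_newick(t1) == canonical_newick(t2)
        # the canonical-smallest serialization of the three 4-taxon
        # topologies (trifurcation anchored at leaf a) pairs b+c
        assert canonical_newick(t1) == "(a,(b,c),d);"

    def test_limit_enforced(self):
        tally = QuartetTally(species=[f"s{i}" for i in range(9)])
        with pytest.raises(ValueError, match="heuristic"):
            exact_search(tally, tally.species, exact_limit=8)

    def test_heuristic_is_deterministic_and_locally_optimal(self, rng):
        trees = [
            random_binary_tree([f"s{i}|g" for i in range(8)], rng, rooted=False)
            for _ in range(6)
        ]
        tally = tally_quartets(trees)
        species = [f"s{i}" for i in range(8)]
        t1 = heuristic_search(tally, species, seed=5)
        t2 = heuristic_search(tally, species, seed=5)
        assert canonical_newick(t1) == canonical_newick(t2)

    def test_heuristic_matches_exact_on_small_instances(self, rng):
        hits = 0
        for trial in range(6):
            trees = [
                random_binary_tree([f"s{i}|g" for i in range(7)], rng, rooted=False)
                for _ in range(5)
            ]
            tally = tally_quartets(trees)
            species = [f"s{i}" for i in range(7)]
            exact = quartet_score(exact_search(tally, species), tally)
            heur = quartet_score(heuristic_search(tally, species, seed=trial), tally)
            assert heur <= exact + 1e-9
            hits += heur == pytest.approx(exact)
        assert hits >= 5


class TestAnnotate:
    def _tally_unanimous(self, n_genes=4):
        gt = gtree("((s0|g,s1|g),((s2|g,s3|g),(s4|g,s5|g)));")
        return tally_quartets([gt] * n_genes)

    def test_unanimous_support_capped_length(self):
        tally = self._tally_unanimous()
        tree = species_newick("((s0,s1),((s2,s3),(s4,s5)));")
        tree.rooted = False
        res = annotate_branches(tree, tally)
        for node in res.tree.root.walk():
            if node is res.tree.root or node.is_leaf:
                continue
            assert node.support == pytest.approx(1.0)
            assert node.length == pytest.approx(10.0)
        for leaf in res.tree.leaves():
            assert leaf.length == pytest.approx(1.0)

    def test_length_formula_values(self):
        # q = 0.9 -> -ln(0.15); q = 1/3 -> 0
        assert -math.log(1.5 * (1 - 0.9)) == pytest.approx(1.8971, abs=1e-4)
        species = ["a", "b", "c", "d"]
        tally = QuartetTally(species=species)
        qmask = 0b1111
        w = np.zeros(3)
        idx_ab = 0  # ab|cd
        w[idx_ab] = 0.9
        w[1] = 0.05
        w[2] = 0.05
        tally.weights[qmask] = w
        tally.n_genes_covering[qmask] = 1
        tree = species_newick("((a,b),(c,d));")
        tree.rooted = False
        res = annotate_branches(tree, tally)
        internal = [
            n for n in res.tree.root.walk()
            if n is not res.tree.root and not n.is_leaf
        ]
        assert internal[0].support == pytest.approx(0.9)
        assert internal[0].length == pytest.approx(-math.log(0.15), abs=1e-9)

    def test_no_signal_gives_zero_length(self):
        species = ["a", "b", "c", "d"]
        tally = QuartetTally(species=species)
        tally.weights[0b1111] = np.full(3, 1 / 3)
        tally.n_genes_covering[0b1111] = 1
        tree = species_newick("((a,b),(c,d));")
        tree.rooted = False
        res = annotate_branches(tree, tally)
        internal = [
            n for n in res.tree.root.walk()
            if n is not res.tree.root and not n.is_leaf
        ]
        assert internal[0].length == pytest.approx(0.0)
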