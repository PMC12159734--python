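"""Species-tree estimation by quartet-score maximization.

The multispecies coalescent predicts that, for any four species, the
unrooted quartet topology of the true species tree is the most frequent
topology among gene trees.  The species tree is therefore estimated by
maximizing the quartet score: the (weighted) number of gene-tree quartets
that agree with the candidate.  Gene trees may be multicopy (several leaves
per species); every combination of one leaf per species contributes
fractionally so that each gene tree carries total weight 1 per covered
quartet — a uniform per-copy weighting rather than duplication-tagged
scoring.

The objective is optimized exactly for small species counts (exhaustive
enumeration of unrooted topologies, feasible through ``exact_limit``
species) and by seeded greedy insertion plus nearest-neighbor-interchange
hill climbing above that.  Internal branches are annotated with the
dominant quartet frequency ``q`` as support and a coalescent-unit length

    d = -ln(1.5 * (1 - q)),   0 when q <= 1/3,  capped at 10

(terminal branches have no discordance signal and are fixed at 1.0).
Species that appear in no sampled group cannot be placed and are reported
as omitted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import log
from typing import Optional, Sequence

import numpy as np

from .formats_io import Tree, TreeNode, canonical_newick, species_of, unroot

logger = logging.getLogger(__name__)

EXACT_LIMIT = 8  # 10395 unrooted topologies at n=8
LENGTH_CAP = 10.0
_TOL = 1e-9


# ---------------------------------------------------------------------------
# quartet tallying
# ---------------------------------------------------------------------------

@dataclass
class QuartetTally:
    """Per-quartet topology weights, the objective's sufficient statistic.

    For the 4-subset with bitmask ``q`` over ``species`` (sorted), entry
    ``weights[q]`` holds three weights for the topologies wx|yz, wy|xz,
    wz|xy (w<x<y<z by species order); their sum equals the number of gene
    trees covering all four species.
    """

    species: list[str]
    weights: dict[int, np.ndarray] = field(default_factory=dict)
    n_genes_covering: dict[int, int] = field(default_factory=dict)
    # pairmask -> topology index, per quartet mask
    _pair_index: dict[int, dict[int, int]] = field(default_factory=dict, repr=False)

    def bit(self, sp: str) -> int:
        return 1 << self.species.index(sp)

    def pair_index(self, qmask: int) -> dict[int, int]:
        cached = self._pair_index.get(qmask)
        if cached is not None:
            return cached
        bits = [1 << b for b in range(len(self.species)) if qmask >> b & 1]
        w, x, y, z = bits
        table = {
            w | x: 0, y | z: 0,
            w | y: 1, x | z: 1,
            w | z: 2, x | y: 2,
        }
        self._pair_index[qmask] = table
        return table


def _leaf_distances(tree: Tree) -> tuple[list[TreeNode], np.ndarray]:
    """Topological distances between all leaves (path edge counts)."""
    nodes = list(tree.root.walk())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for n in nodes:
        for c in n.children:
            adj[index[id(n)]].append(index[id(c)])
            adj[index[id(c)]].append(index[id(n)])
    leaves = [n for n in nodes if n.is_leaf]
    leaf_idx = [index[id(n)] for n in leaves]
    dist = np.zeros((len(leaves), len(leaves)), dtype=np.int32)
    for li, src in enumerate(leaf_idx):
        d = np.full(len(nodes), -1, dtype=np.int32)
        d[src] = 0
        stack = [src]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if d[v] < 0:
                    d[v] = d[u] + 1
                    stack.append(v)
        for lj, dst in enumerate(leaf_idx):
            dist[li, lj] = d[dst]
    return leaves, dist


def _induced_topology(dm: np.ndarray, a: int, b: int, c: int, d: int) -> int:
    """0: ab|cd, 1: ac|bd, 2: ad|bc, -1: unresolved (tied path lengths)."""
    s0 = dm[a, b] + dm[c, d]
    s1 = dm[a, c] + dm[b, d]
    s2 = dm[a, d] + dm[b, c]
    m = min(s0, s1, s2)
    winners = [k for k, s in enumerate((s0, s1, s2)) if s == m]
    return winners[0] if len(winners) == 1 else -1


def tally_quartets(
    gene_trees: Sequence[Tree],
    max_samples_per_quartet: int = 100,
    seed: int = 0,
) -> QuartetTally:
    """Aggregate quartet topology weights over (possibly multicopy) gene
    trees.  Per gene tree and 4-species subset, all one-leaf-per-species
    combinations are enumerated when there are at most
    ``max_samples_per_quartet`` of them, otherwise that many are sampled
    with the seeded RNG; each combination contributes equally so the gene
    tree adds total weight 1.  Trees covering fewer than 4 species
    contribute nothing."""
    all_species = sorted(
        {species_of(lbl) for t in gene_trees for lbl in t.leaf_labels()}
    )
    tally = QuartetTally(species=all_species)
    rng = np.random.default_rng(seed)
    for tree in gene_trees:
        leaves, dm = _leaf_distances(tree)
        by_species: dict[str, list[int]] = {}
        for i, leaf in enumerate(leaves):
            by_species.setdefault(species_of(leaf.label), []).append(i)
        present = sorted(by_species)
        if len(present) < 4:
            continue
        for quad in itertools.combinations(present, 4):
            qmask = 0
            for sp in quad:
                qmask |= tally.bit(sp)
            pools = [by_species[sp] for sp in quad]
            n_comb = int(np.prod([len(p) for p in pools]))
            if n_comb <= max_samples_per_quartet:
                combos = itertools.product(*pools)
                weight = 1.0 / n_comb
            else:
                combos = (
                    tuple(pool[rng.integers(len(pool))] for pool in pools)
                    for _ in range(max_samples_per_quartet)
                )
                weight = 1.0 / max_samples_per_quartet
            w = tally.weights.setdefault(qmask, np.zeros(3))
            for a, b, c, d in combos:
                t = _induced_topology(dm, a, b, c, d)
                if t < 0:
                    w += weight / 3.0
                else:
                    w[t] += weight
            tally.n_genes_covering[qmask] = tally.n_genes_covering.get(qmask, 0) + 1
    return tally


# ---------------------------------------------------------------------------
# scoring candidates
# ---------------------------------------------------------------------------

def _tree_split_masks(tree: Tree, tally: QuartetTally) -> list[int]:
    """Bitmask (over tally.species) of the leaf set under every node with a
    non-trivial split."""
    n = len(tally.species)
    masks: list[int] = []

    def rec(node: TreeNode) -> int:
        if node.is_leaf:
            return tally.bit(node.label)
        m = 0
        for c in node.children:
            m |= rec(c)
        masks.append(m)
        return m

    rec(tree.root)
    return [m for m in masks if 2 <= bin(m).count("1") <= n - 2]


def _score_split_masks(masks: Sequence[int], tally: QuartetTally) -> float:
    total = 0.0
    for qmask, w in tally.weights.items():
        pair = 0
        for s in masks:
            inter = s & qmask
            if bin(inter).count("1") == 2:
                pair = inter
                break
        if pair:
            total += w[tally.pair_index(qmask)[pair]]
    return total


def quartet_score(candidate: Tree, tally: QuartetTally) -> float:
    """Summed weight of the gene-tree quartet topologies the candidate
    induces.  The candidate must be binary and cover all tallied species."""
    cand_species = set(candidate.leaf_labels())
    missing = set(tally.species) - cand_species
    if missing:
        raise ValueError(f"candidate tree missing tallied species: {sorted(missing)}")
    return _score_split_masks(_tree_split_masks(candidate, tally), tally)


# ---------------------------------------------------------------------------
# search over topologies
# ---------------------------------------------------------------------------
# Unrooted binary topologies over species indices 0..n-1 are represented as
# a nested tuple: the subtree opposite leaf 0, rooted at leaf 0's neighbor.
# Each tuple node is an internal vertex; inserting leaf k on every edge of
# the representation enumerates every topology exactly once.

def _masks_of_nested(t, n: int, out: list[int]) -> int:
    if isinstance(t, int):
        return 1 << t
    m = _masks_of_nested(t[0], n, out) | _masks_of_nested(t[1], n, out)
    if 2 <= bin(m).count("1") <= n - 2:
        out.append(m)
    return m


def _nested_to_tree(t, species: list[str]) -> Tree:
    def rec(node) -> TreeNode:
        if isinstance(node, int):
            return TreeNode(label=species[node])
        tn = TreeNode()
        tn.add(rec(node[0]))
        tn.add(rec(node[1]))
        return tn

    root = TreeNode()
    root.add(TreeNode(label=species[0]))
    if isinstance(t, int):
        root.add(rec(t))
    else:
        root.add(rec(t[0]))
        root.add(rec(t[1]))
    return Tree(root, rooted=False)


def _insertions(t, leaf):
    """All topologies with ``leaf`` attached to one edge of ``t``."""
    yield (t, leaf)
    if isinstance(t, tuple):
        for left in _insertions(t[0], leaf):
            yield (left, t[1])
        for right in _insertions(t[1], leaf):
            yield (t[0], right)


def _nni_variants(t):
    """All topologies one nearest-neighbor interchange away."""
    if not isinstance(t, tuple):
        return
    left, right = t
    if isinstance(left, tuple):
        yield ((left[0], right), left[1])
        yield ((left[1], right), left[0])
    if isinstance(right, tuple):
        yield ((right[0], left), right[1])
        yield ((right[1], left), right[0])
    for v in _nni_variants(left):
        yield (v, right)
    for v in _nni_variants(right):
        yield (left, v)


def _score_nested(t, n: int, tally: QuartetTally) -> float:
    masks: list[int] = []
    _masks_of_nested(t, n, masks)
    return _score_split_masks(masks, tally)


def _n_unrooted_topologies(n: int) -> int:
    out = 1
    for k in range(5, 2 * n - 4, 2):
        out *= k
    return out


def exact_search(tally: QuartetTally, species: Sequence[str],
                 exact_limit: int = EXACT_LIMIT) -> Tree:
    """Maximum-quartet-score tree by full enumeration of unrooted binary
    topologies; ties broken by smallest canonical Newick string."""
    species = sorted(species)
    n = len(species)
    if n > exact_limit:
        raise ValueError(
            f"{n} species exceeds exact_limit={exact_limit} "
            f"({_n_unrooted_topologies(n)} topologies); use heuristic_search"
        )
    if n < 4:
        raise ValueError("need at least 4 species for an informative tree")
    _check_species(tally, species)

    best_score = -1.0
    best_key = None
    best_tree = None

    def consider(t):
        nonlocal best_score, best_key, best_tree
        score = _score_nested(t, n, tally)
        if score > best_score + _TOL:
            best_score, best_tree = score, t
            best_key = canonical_newick(_nested_to_tree(t, species))
        elif abs(score - best_score) <= _TOL:
            key = canonical_newick(_nested_to_tree(t, species))
            if key < best_key:
                best_tree, best_key = t, key

    def enumerate_trees(t, next_leaf):
        if next_leaf == n:
            consider(t)
            return
        for t2 in _insertions(t, next_leaf):
            enumerate_trees(t2, next_leaf + 1)

    enumerate_trees((1, 2), 3)
    logger.debug("exact search: best quartet score %.4f", best_score)
    return _nested_to_tree(best_tree, species)


def heuristic_search(
    tally: QuartetTally,
    species: Sequence[str],
    restarts: int = 3,
    seed: int = 0,
) -> Tree:
    """Greedy stepwise insertion in a random (seeded) leaf order followed by
    NNI hill climbing; best of ``restarts`` restarts.  Deterministic for a
    fixed seed."""
    species = sorted(species)
    n = len(species)
    if n < 4:
        raise ValueError("need at least 4 species for an informative tree")
    _check_species(tally, species)
    rng = np.random.default_rng(seed)
    best_overall = None  # (score, canonical key, nested)
    for _ in range(restarts):
        order = [int(k) for k in rng.permutation(n)]
        # representation stays anchored at leaf 0; the permutation decides
        # the insertion order of the remaining leaves
        rest = [k for k in order if k != 0]
        current = (rest[0], rest[1])
        for leaf in rest[2:]:
            best = None
            for t2 in _insertions(current, leaf):
                score = _score_nested(t2, n, tally)
                if best is None or score > best[0] + _TOL:
                    best = (score, t2)
            current = best[1]
        current_score = _score_nested(current, n, tally)
        # NNI hill climbing to a local optimum
        improved = True
        while improved:
            improved = False
            for t2 in _nni_variants(current):
                score = _score_nested(t2, n, tally)
                if score > current_score + _TOL:
                    current, current_score = t2, score
                    improved = True
                    break
        key = canonical_newick(_nested_to_tree(current, species))
        cand = (current_score, key, current)
        if (
            best_overall is None
            or cand[0] > best_overall[0] + _TOL
            or (abs(cand[0] - best_overall[0]) <= _TOL and cand[1] < best_overall[1])
        ):
            best_overall = cand
    return _nested_to_tree(best_overall[2], species)


def _check_species(tally: QuartetTally, species: Sequence[str]) -> None:
    extra = set(tally.species) - set(species)
    if extra:
        raise ValueError(f"tally covers species not in the search set: {sorted(extra)}")


# ---------------------------------------------------------------------------
# branch annotation
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeResult:
    """Final species tree with quartet support and coalescent-unit branch
    lengths, plus the species that could not be placed."""

    tree: Tree
    omitted_species: list[str] = field(default_factory=list)


def _subtree_species(node: TreeNode) -> set[str]:
    return {n.label for n in node.walk() if n.is_leaf}


def annotate_branches(tree: Tree, tally: QuartetTally,
                      omitted_species: Optional[list[str]] = None) -> SpeciesTreeResult:
    """Attach per-branch support (dominant quartet frequency ``q``) and
    coalescent-unit length to every internal branch of a binary unrooted
    species tree; terminal branches get length 1.0.  A binary-rooted input
    is unrooted first (the two root edges are one unrooted branch)."""
    tree = unroot(tree) if len(tree.root.children) == 2 else tree.copy()
    for node in tree.root.walk():
        if node is tree.root:
            continue
        if node.is_leaf:
            node.length = 1.0
            continue
        # the four species groups around the branch above `node`
        a, b = (_subtree_species(c) for c in node.children)
        parent = node.parent
        sibs = [c for c in parent.children if c is not node]
        if parent is tree.root and len(sibs) == 2:
            c_set = _subtree_species(sibs[0])
            d_set = _subtree_species(sibs[1])
        else:
            c_set = _subtree_species(sibs[0]) if sibs else set()
            rest = set(tree.leaf_labels()) - a - b - c_set
            d_set = rest
        if not (a and b and c_set and d_set):
            node.length = 0.0
            continue
        agree = 0.0
        total = 0.0
        for wsp, xsp, ysp, zsp in itertools.product(a, b, c_set, d_set):
            qmask = tally.bit(wsp) | tally.bit(xsp) | tally.bit(ysp) | tally.bit(zsp)
            w = tally.weights.get(qmask)
            if w is None:
                continue
            agree += w[tally.pair_index(qmask)[tally.bit(wsp) | tally.bit(xsp)]]
            total += float(w.sum())
        if total <= 0:
            q = 1.0 / 3.0
        else:
            q = agree / total
        node.support = q
        node.length = 0.0 if q <= 1.0 / 3.0 else min(-log(1.5 * (1.0 - q)) if q < 1.0 else LENGTH_CAP, LENGTH_CAP)
    return SpeciesTreeResult(tree=tree, omitted_species=list(omitted_species or []))
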