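"""Tree-comparison metrics: Robinson-Foulds and rooted triplet distance.

The RF distance counts bipartitions (splits) present in exactly one of two
trees and is reported normalized to a percentage: 0% for identical split
sets, 100% when no split is shared.  When the reference is not binary
(e.g. a taxonomy with polytomies) a one-sided variant is also reported
that only counts reference splits missing from the estimate — extra
resolution in the estimate is not an inaccuracy when the reference does
not claim to be fully resolved.

The triplet distance compares two *rooted* trees: the fraction of 3-leaf
subsets whose induced rooted topologies are resolved in both trees but
differ.  Reference-unresolved triplets count as agreement by default (the
rooted analogue of the one-sided split convention; switchable).  Because
the pipeline's output trees are unrooted, ``compare_trees`` roots the
estimate at the midpoint of its longest leaf-to-leaf path (or at a given
outgroup) before triplet comparison.

Both metrics are computed on the shared leaf set only, after restricting
each tree to it; branch lengths never enter any metric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

from .formats_io import Tree, TreeNode

logger = logging.getLogger(__name__)


@dataclass
class TreeComparison:
    rf_raw: int
    rf_normalized: float  # percent in [0, 100]
    one_sided_rf: float  # percent; reference splits missing from estimate
    triplet_error: Optional[float]  # fraction in [0, 1]; None if not computed
    n_shared_leaves: int


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def bipartitions(tree: Tree) -> set[frozenset]:
    """Non-trivial splits of a tree, each canonicalized as the side that
    does not contain the lexicographically smallest leaf."""
    labels = tree.leaf_labels()
    n = len(labels)
    if n < 4:
        return set()
    smallest = min(labels)
    all_leaves = frozenset(labels)
    out: set[frozenset] = set()

    def rec(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset((node.label,))
        below = frozenset().union(*(rec(c) for c in node.children))
        if 2 <= len(below) <= n - 2:
            side = all_leaves - below if smallest in below else below
            out.add(side)
        return below

    rec(tree.root)
    return out


def restrict(tree: Tree, keep: set[str]) -> Tree:
    """Copy of the tree restricted to a leaf subset, with unary nodes
    suppressed (their branch lengths summed)."""

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.label in keep:
                return TreeNode(node.label, node.length, node.support)
            return None
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            k = kids[0]
            if node.length is not None or k.length is not None:
                k.length = (node.length or 0.0) + (k.length or 0.0)
            return k
        new = TreeNode(None, node.length, node.support)
        if node.is_leaf is False and node.label and node.support is None:
            new.label = node.label
        for k in kids:
            new.add(k)
        return new

    root = prune(tree.root)
    if root is None:
        raise ValueError("restriction removed every leaf")
    root.length = None
    return Tree(root, rooted=tree.rooted)


def is_binary_unrooted(tree: Tree) -> bool:
    """A tree is fully resolved iff it has n-3 non-trivial splits."""
    n = len(tree.leaf_labels())
    return len(bipartitions(tree)) == n - 3


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def rf_distance(t1: Tree, t2: Tree) -> TreeComparison:
    """Robinson-Foulds distance of two trees on their shared leaf set.

    ``t1`` is treated as the reference for the one-sided variant.
    """
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    shared = l1 & l2
    if not shared:
        raise ValueError("trees share no leaves")
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared leaves; need >= 4 for splits")
    if shared != l1 or shared != l2:
        logger.info(
            "restricting comparison to %d shared leaves (%d and %d total)",
            len(shared), len(l1), len(l2),
        )
    s1 = bipartitions(restrict(t1, shared))
    s2 = bipartitions(restrict(t2, shared))
    raw = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    normalized = 100.0 * raw / denom if denom else 0.0
    one_sided = 100.0 * len(s1 - s2) / len(s1) if s1 else 0.0
    return TreeComparison(
        rf_raw=raw,
        rf_normalized=normalized,
        one_sided_rf=one_sided,
        triplet_error=None,
        n_shared_leaves=len(shared),
    )


# ---------------------------------------------------------------------------
# rooted triplets
# ---------------------------------------------------------------------------

def _triplet_tables(tree: Tree):
    """Leaf list plus a pairwise LCA-depth table."""
    depth: dict[int, int] = {}
    parent: dict[int, TreeNode] = {}

    def walk(node: TreeNode, d: int):
        depth[id(node)] = d
        for c in node.children:
            parent[id(c)] = node
            walk(c, d + 1)

    walk(tree.root, 0)
    leaves = {n.label: n for n in tree.leaves()}

    def lca_depth(a: TreeNode, b: TreeNode) -> int:
        x, y = a, b
        while id(x) != id(y):
            if depth[id(x)] >= depth[id(y)]:
                x = parent[id(x)]
            else:
                y = parent[id(y)]
        return depth[id(x)]

    return leaves, lca_depth


def _induced_triplet(lca_depth, la, lb, lc) -> int:
    """0: ((a,b),c)  1: ((a,c),b)  2: ((b,c),a)  -1: unresolved."""
    dab = lca_depth(la, lb)
    dac = lca_depth(la, lc)
    dbc = lca_depth(lb, lc)
    m = max(dab, dac, dbc)
    winners = [k for k, d in enumerate((dab, dac, dbc)) if d == m]
    return winners[0] if len(winners) == 1 else -1


def triplet_distance(
    rooted_ref: Tree,
    rooted_est: Tree,
    penalize_extra_resolution: bool = False,
) -> float:
    """Fraction of 3-leaf subsets (of the shared leaf set) on which the two
    rooted trees disagree.  Triplets unresolved in the reference count as
    agreement unless ``penalize_extra_resolution``."""
    for name, t in (("reference", rooted_ref), ("estimate", rooted_est)):
        if not t.rooted:
            raise ValueError(
                f"{name} tree is unrooted; root it first "
                "(e.g. midpoint_root or an outgroup)"
            )
    shared = set(rooted_ref.leaf_labels()) & set(rooted_est.leaf_labels())
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared leaves; need >= 3")
    ref = restrict(rooted_ref, shared)
    est = restrict(rooted_est, shared)
    ref_leaves, ref_lca = _triplet_tables(ref)
    est_leaves, est_lca = _triplet_tables(est)
    mismatches = 0
    count = 0
    for a, b, c in itertools.combinations(sorted(shared), 3):
        count += 1
        tr = _induced_triplet(ref_lca, ref_leaves[a], ref_leaves[b], ref_leaves[c])
        te = _induced_triplet(est_lca, est_leaves[a], est_leaves[b], est_leaves[c])
        if tr >= 0:
            if te >= 0 and te != tr:
                mismatches += 1
        elif penalize_extra_resolution and te >= 0:
            mismatches += 1
    return mismatches / count if count else 0.0


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _blen(node: TreeNode) -> float:
    return node.length if node.length is not None else 1.0


def _copy_down(node: TreeNode) -> TreeNode:
    new = TreeNode(node.label, node.length, node.support)
    for c in node.children:
        new.add(_copy_down(c))
    return new


def _suppress_unary(node: TreeNode) -> TreeNode:
    while len(node.children) == 1:
        child = node.children[0]
        if node.length is not None or child.length is not None:
            child.length = (node.length or 0.0) + (child.length or 0.0)
        node = child
        node.parent = None
    node.children = [_suppress_unary(c) for c in node.children]
    for c in node.children:
        c.parent = node
    return node


def _rebuild_up(node: TreeNode, exclude: TreeNode) -> TreeNode:
    """The tree as seen looking 'up' from one of node's edges: node with its
    other neighbors (children and parent) as children."""
    new = TreeNode(node.label, None, node.support)
    for c in node.children:
        if c is not exclude:
            new.add(_copy_down(c))
    if node.parent is not None:
        up = _rebuild_up(node.parent, exclude=node)
        up.length = node.length
        new.add(up)
    return new


def reroot_on_edge(tree: Tree, child: TreeNode, dist_from_child: float) -> Tree:
    """Root the tree on the edge above ``child``, at the given distance from
    ``child`` (clamped into the edge)."""
    if child.parent is None:
        raise ValueError("cannot reroot on the root node")
    L = _blen(child)
    d = min(max(dist_from_child, 0.0), L)
    root = TreeNode()
    below = _copy_down(child)
    below.length = d
    above = _rebuild_up(child.parent, exclude=child)
    above.length = L - d
    root.add(below)
    root.add(above)
    root.children = [_suppress_unary(c) for c in root.children]
    for c in root.children:
        c.parent = root
    return Tree(root, rooted=True)


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path (missing
    branch lengths count as 1)."""
    # distances from every leaf via the node adjacency
    nodes = list(tree.root.walk())
    leaves = [n for n in nodes if n.is_leaf]
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")

    def farthest(src: TreeNode):
        dist = {id(src): 0.0}
        prev: dict[int, TreeNode] = {}
        stack = [src]
        node_by_id = {id(n): n for n in nodes}
        while stack:
            u = stack.pop()
            neigh = list(u.children)
            if u.parent is not None:
                neigh.append(u.parent)
            for v in neigh:
                if id(v) in dist:
                    continue
                w = _blen(v) if v.parent is u else _blen(u)
                dist[id(v)] = dist[id(u)] + w
                prev[id(v)] = u
                stack.append(v)
        best = max(leaves, key=lambda l: (dist[id(l)], l.label))
        return best, dist, prev

    u, _, _ = farthest(leaves[0])
    v, dist, prev = farthest(u)
    # walk back from v to u accumulating length until the midpoint
    path = [v]
    while id(path[-1]) != id(u):
        path.append(prev[id(path[-1])])
    half = dist[id(v)] / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        # edge between a and b: one is the parent of the other
        child = a if a.parent is b else b
        w = _blen(child)
        if acc + w >= half - 1e-12:
            offset = half - acc  # distance from `a` along this edge
            d_from_child = offset if child is a else w - offset
            return reroot_on_edge(tree, child, d_from_child)
        acc += w
    return reroot_on_edge(tree, path[-2] if path[-2].parent is u else u, 0.0)


def root_at_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root on the terminal edge of the named leaf, at its midpoint."""
    for leaf in tree.leaves():
        if leaf.label == outgroup:
            return reroot_on_edge(tree, leaf, _blen(leaf) / 2.0)
    raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")


# ---------------------------------------------------------------------------
# combined comparison
# ---------------------------------------------------------------------------

def compare_trees(
    ref: Tree,
    est: Tree,
    outgroup: Optional[str] = None,
) -> TreeComparison:
    """RF plus triplet comparison of an estimate against a reference.

    The reference is used as rooted if it is; the estimate is rooted at the
    midpoint (or at ``outgroup``) for the triplet metric when needed.
    """
    cmp = rf_distance(ref, est)
    ref_rooted = ref if ref.rooted else midpoint_root(ref)
    if outgroup is not None:
        est_rooted = root_at_outgroup(est, outgroup)
    elif est.rooted:
        est_rooted = est
    else:
        est_rooted = midpoint_root(est)
    cmp.triplet_error = triplet_distance(ref_rooted, est_rooted)
    return cmp
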