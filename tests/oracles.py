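"""Independent reference implementations used only for cross-checking.

Everything here is deliberately naive (full matrices, explicit
enumeration, BFS over adjacency) and structurally different from the
package's implementations, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

from sylva.formats_io import Tree, TreeNode

NEG = float("-inf")


# ---------------------------------------------------------------------------
# alignment oracles
# ---------------------------------------------------------------------------

def sw_local_score(a: str, b: str, match, mismatch, gap_open, gap_extend) -> int:
    """Full-matrix Smith-Waterman-Gotoh local score (no band, no tricks).

    Opening a gap costs gap_open + gap_extend; each extension gap_extend.
    N scores 0 against anything.
    """
    m, n = len(a), len(b)
    go = gap_open + gap_extend
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if a[i - 1] == "N" or b[j - 1] == "N":
                s = 0
            elif a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - go)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - go)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def global_affine_score(a: str, b: str, match, mismatch, gap_open, gap_extend) -> float:
    """Full-matrix global (end-gaps penalized) affine alignment score."""
    m, n = len(a), len(b)
    go = gap_open + gap_extend
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    for j in range(1, n + 1):
        E[0][j] = max(E[0][j - 1] - gap_extend, H[0][j - 1] - go)
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = max(F[i - 1][0] - gap_extend, H[i - 1][0] - go)
        H[i][0] = F[i][0]
        for j in range(1, n + 1):
            if a[i - 1] == "N" or b[j - 1] == "N":
                s = 0
            elif a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - go)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - go)
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[m][n]


# ---------------------------------------------------------------------------
# ORF oracle
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def orf_enumeration(seq: str, min_len: int):
    """All complete ORFs by explicit frame walking on both strands.

    Returns a set of (fwd_start, fwd_end, strand) tuples.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else "".join(comp[c] for c in reversed(seq))
        n = len(s)
        for frame in range(3):
            codon_starts = list(range(frame, n - 2, 3))
            stops = [i for i in codon_starts if s[i : i + 3] in _STOPS]
            prev = frame - 3
            for stop in stops:
                atgs = [
                    i for i in codon_starts
                    if prev < i < stop and s[i : i + 3] == "ATG"
                ]
                if atgs:
                    start = min(atgs)
                    if stop + 3 - start >= min_len:
                        if strand == "+":
                            out.add((start, stop + 3, "+"))
                        else:
                            out.add((n - (stop + 3), n - start, "-"))
                prev = stop
    return out


# ---------------------------------------------------------------------------
# DBSCAN oracle
# ---------------------------------------------------------------------------

def naive_dbscan(ids, D, eps, min_pts):
    """Classic textbook DBSCAN: seed-point expansion with an explicit
    queue, visiting ids in sorted order.  Border points are claimed by
    their first core neighbor in sorted order (the same deterministic
    convention the implementation documents)."""
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    neighbors = {
        i: [j for j in order if D[i][j] <= eps] for i in range(len(ids))
    }
    core = {i for i in range(len(ids)) if len(neighbors[i]) >= min_pts}
    labels = {i: None for i in range(len(ids))}
    cluster = -1
    for i in order:
        if i not in core or labels[i] is not None:
            continue
        cluster += 1
        queue = [i]
        labels[i] = cluster
        while queue:
            u = queue.pop(0)
            for v in neighbors[u]:
                if v in core and labels[v] is None:
                    labels[v] = cluster
                    queue.append(v)
    for i in order:
        if labels[i] is not None:
            continue
        for j in order:
            if j != i and j in core and D[i][j] <= eps:
                labels[i] = labels[j]
                break
    return {ids[i]: (-1 if labels[i] is None else labels[i]) for i in range(len(ids))}


# ---------------------------------------------------------------------------
# tree oracles
# ---------------------------------------------------------------------------

def splits_by_edge_removal(tree: Tree) -> set[frozenset]:
    """Non-trivial splits by literally deleting each edge and flooding the
    two components of the node adjacency graph."""
    nodes = list(tree.root.walk())
    idx = {id(n): k for k, n in enumerate(nodes)}
    edges = []
    adj = {k: set() for k in range(len(nodes))}
    for n in nodes:
        for c in n.children:
            a, b = idx[id(n)], idx[id(c)]
            adj[a].add(b)
            adj[b].add(a)
            edges.append((a, b))
    leaves = {idx[id(n)]: n.label for n in nodes if n.is_leaf}
    all_labels = frozenset(leaves.values())
    smallest = min(all_labels)
    out = set()
    for a, b in edges:
        seen = {b}
        stack = [b]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if {u, v} == {a, b} or v in seen:
                    continue
                seen.add(v)
                stack.append(v)
        side = frozenset(leaves[k] for k in seen if k in leaves)
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(all_labels - side if smallest in side else side)
    return out


def clade_sets(tree: Tree) -> list[frozenset]:
    out = []

    def rec(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset((node.label,))
        below = frozenset().union(*(rec(c) for c in node.children))
        out.append(below)
        return below

    rec(tree.root)
    return out


def rooted_triplet(clades: list[frozenset], a: str, b: str, c: str) -> int:
    """0: ((a,b),c)  1: ((a,c),b)  2: ((b,c),a)  -1: unresolved.

    A pair is a cherry of the triplet iff some clade contains it but not
    the third leaf.
    """
    for k, (x, y, z) in enumerate(((a, b, c), (a, c, b), (b, c, a))):
        if any(x in cl and y in cl and z not in cl for cl in clades):
            return k
    return -1


def quartet_topology_by_splits(splits: set[frozenset], w, x, y, z) -> int:
    """0: wx|yz  1: wy|xz  2: wz|xy  -1: unresolved, from a tree's full
    split set (trivial splits excluded are irrelevant: any separating
    split works)."""
    quartet = {w, x, y, z}
    for s in splits:
        inter = s & quartet
        if len(inter) == 2:
            if inter in ({w, x}, {y, z}):
                return 0
            if inter in ({w, y}, {x, z}):
                return 1
            return 2
    return -1


def all_splits_with_trivial(tree: Tree) -> set[frozenset]:
    """Every split (including sides of size 1..n-1) as the side below each
    edge, uncanonicalized — used for quartet separation checks."""
    out = set()

    def rec(node: TreeNode) -> frozenset:
        if node.is_leaf:
            below = frozenset((node.label,))
        else:
            below = frozenset().union(*(rec(c) for c in node.children))
        out.add(below)
        return below

    rec(tree.root)
    return out


# ---------------------------------------------------------------------------
# random tree generation
# ---------------------------------------------------------------------------

def random_binary_tree(labels, rng, rooted=True, min_len=0.1, max_len=2.0) -> Tree:
    """Random topology by repeatedly joining two random subtrees."""
    nodes = [TreeNode(label=l) for l in labels]
    for node in nodes:
        node.length = float(rng.uniform(min_len, max_len))
    while len(nodes) > (2 if rooted else 3):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(min_len, max_len)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add(n)
    return Tree(root, rooted=rooted)


def path_length_matrix(tree: Tree):
    """Leaf-to-leaf path lengths (branch-length weighted) by DFS."""
    nodes = list(tree.root.walk())
    idx = {id(n): k for k, n in enumerate(nodes)}
    adj = {k: [] for k in range(len(nodes))}
    for n in nodes:
        for c in n.children:
            w = c.length if c.length is not None else 1.0
            adj[idx[id(n)]].append((idx[id(c)], w))
            adj[idx[id(c)]].append((idx[id(n)], w))
    leaf_ids = sorted([n.label for n in nodes if n.is_leaf])
    leaf_idx = {n.label: idx[id(n)] for n in nodes if n.is_leaf}
    D = np.zeros((len(leaf_ids), len(leaf_ids)))
    for i, la in enumerate(leaf_ids):
        dist = {leaf_idx[la]: 0.0}
        stack = [leaf_idx[la]]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, lb in enumerate(leaf_ids):
            D[i, j] = dist[leaf_idx[lb]]
    return leaf_ids, D
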