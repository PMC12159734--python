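"""Gene-tree construction: Jukes-Cantor distances + neighbor joining.

One tree is built per aligned homolog group.  Distances between rows are
Jukes-Cantor corrected mismatch fractions,

    d = -(3/4) * ln(1 - (4/3) p)

computed over columns where both rows carry a plain base; saturated pairs
(p >= 3/4, or no comparable column) are set to ``d_max`` (default 5.0
substitutions/site) to keep neighbor joining finite.  NJ is the standard
Q-criterion algorithm with Saitou-Nei branch lengths, negative estimates
clamped to zero, and ties on Q broken toward the lexicographically smallest
pair of cluster representatives so the output is reproducible.

Leaves keep their gene ids, so a species may appear several times in one
tree (multicopy); the species-tree stage resolves that.  An external
maximum-likelihood tree builder can stand behind the same interface
(alignment in, Newick out).
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np

from .formats_io import Tree, TreeNode
from .homolog_grouping import DistanceMatrix

logger = logging.getLogger(__name__)

D_MAX = 5.0  # substitutions/site assigned to saturated pairs

_BASES = frozenset("ACGT")


def jc_distance(row_i: str, row_j: str, d_max: float = D_MAX) -> float:
    """Jukes-Cantor distance between two alignment rows."""
    comparable = 0
    mismatches = 0
    for a, b in zip(row_i, row_j):
        if a in _BASES and b in _BASES:
            comparable += 1
            if a != b:
                mismatches += 1
    if comparable == 0:
        return d_max
    p = mismatches / comparable
    if p >= 0.75:
        return d_max
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def nj(D: DistanceMatrix) -> Tree:
    """Neighbor joining over a symmetric zero-diagonal distance matrix.

    Returns an unrooted tree (trifurcating top node) with clamped
    non-negative branch lengths.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = {i: {j: float(D.d[i][j]) for j in range(n) if j != i} for i in range(n)}
    nodes: dict[int, TreeNode] = {i: TreeNode(label=D.ids[i]) for i in range(n)}
    rep: dict[int, str] = {i: D.ids[i] for i in range(n)}  # smallest leaf label
    active = sorted(d, key=lambda i: rep[i])
    next_id = n
    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i][j] - R[i] - R[j]
                key = tuple(sorted((rep[i], rep[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key)
                    best_pair = (i, j)
        i, j = best_pair
        li = 0.5 * d[i][j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = d[i][j] - li
        u = next_id
        next_id += 1
        node = TreeNode()
        ci = nodes.pop(i)
        cj = nodes.pop(j)
        ci.length = max(0.0, li)
        cj.length = max(0.0, lj)
        node.add(ci)
        node.add(cj)
        nodes[u] = node
        rep[u] = min(rep[i], rep[j])
        d[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
            d[u][k] = duk
            d[k][u] = duk
        active = sorted(
            [k for k in active if k not in (i, j)] + [u], key=lambda x: rep[x]
        )
        del d[i], d[j]
    # join the last three clusters at a trifurcating root
    a, b, c = active
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    root = TreeNode()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(k)
        child.length = max(0.0, lk)
        root.add(child)
    return Tree(root, rooted=False)


def build_gene_tree(msa, d_max: float = D_MAX) -> Optional[Tree]:
    """NJ tree over all-pairs Jukes-Cantor distances of an alignment.

    Groups with fewer than 3 rows cannot form a tree and are skipped with a
    warning (returns None).
    """
    if len(msa.rows) < 3:
        logger.warning(
            "group with %d member(s) skipped: cannot form a tree", len(msa.rows)
        )
        return None
    order = sorted(range(len(msa.ids)), key=lambda k: msa.ids[k])
    ids = [msa.ids[k] for k in order]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = jc_distance(msa.rows[order[i]], msa.rows[order[j]], d_max)
            d[i, j] = d[j, i] = dij
    return nj(DistanceMatrix(ids=ids, d=d))
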