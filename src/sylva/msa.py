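"""Progressive multiple sequence alignment of a homolog group.

Alignment is guided by a neighbor-joining tree built on cheap k-mer profile
distances, then profiles are merged bottom-up by global profile-profile
alignment with affine gaps.  Columns are frequency vectors over
``{A,C,G,T,N,-}``; the score of aligning two columns is the expected pair
score under those frequencies, with ``N`` scoring 0 against everything and
``-`` scoring ``-gap_extend`` against a base (existing gaps are charged
linearly, new gaps through the affine machinery).  Dynamic-programming
ties break toward diagonal, then up (gap in the second profile), then left,
so the output is deterministic.

For two sequences this reduces exactly to global pairwise affine-gap
alignment, which is how the aligner is cross-checked.  No iterative
refinement is attempted; an external aligner can stand behind the same
``Msa`` interface (FASTA in, aligned FASTA out) if preferred.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .formats_io import SeqRecord, write_fasta
from .similarity_search import ScoringParams

# column alphabet indices
_SYM = "ACGTN-"
_SYM_IDX = {c: i for i, c in enumerate(_SYM)}

_NEG = -1e30


@dataclass
class Msa:
    """An alignment: equal-length gapped rows in input-sequence order."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, k: int) -> str:
        return self.rows[k].replace("-", "")


def kmer_profile_distance(a: str, b: str, k: int = 6) -> float:
    """1 - (shared k-mer multiset size) / min(#kmers); 1 if either sequence
    is shorter than k."""
    if len(a) < k or len(b) < k:
        return 1.0
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum((ca & cb).values())
    return 1.0 - shared / min(sum(ca.values()), sum(cb.values()))


def _substitution_matrix(p: ScoringParams) -> np.ndarray:
    """6x6 expected-pair-score matrix over ACGTN- (see module docstring)."""
    S = np.zeros((6, 6), dtype=np.float64)
    for i in range(4):
        for j in range(4):
            S[i, j] = p.match if i == j else p.mismatch
    # N (index 4) scores 0 against everything: already zero
    for i in range(4):
        S[i, 5] = S[5, i] = -float(p.gap_extend)
    return S


def _profile(rows: Sequence[str]) -> np.ndarray:
    L = len(rows[0])
    prof = np.zeros((L, 6), dtype=np.float64)
    for row in rows:
        for j, c in enumerate(row):
            prof[j, _SYM_IDX[c]] += 1.0
    return prof / len(rows)


@njit(cache=True)
def _align_profiles(C, gap_open, gap_extend):
    """Global affine-gap DP over precomputed column-pair scores C (la x lb).

    Returns (score, moves) where moves codes the path backwards:
    1 = diagonal, 2 = up (column of A vs gap), 3 = left (gap vs column of B).
    Opening a gap costs gap_open + gap_extend; tie priority diag > up > left.
    """
    la, lb = C.shape
    go = gap_open + gap_extend
    H = np.full((la + 1, lb + 1), _NEG)
    E = np.full((la + 1, lb + 1), _NEG)  # gap in A (left moves)
    F = np.full((la + 1, lb + 1), _NEG)  # gap in B (up moves)
    # 0 = from H (gap opened), 1 = extension
    ptr_h = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 1 diag, 2 up, 3 left
    ptr_e = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptr_f = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    H[0, 0] = 0.0
    for i in range(1, la + 1):
        open_ = H[i - 1, 0] - go
        ext = F[i - 1, 0] - gap_extend
        if open_ >= ext:
            F[i, 0] = open_
            ptr_f[i, 0] = 0
        else:
            F[i, 0] = ext
            ptr_f[i, 0] = 1
        H[i, 0] = F[i, 0]
        ptr_h[i, 0] = 2
    for j in range(1, lb + 1):
        open_ = H[0, j - 1] - go
        ext = E[0, j - 1] - gap_extend
        if open_ >= ext:
            E[0, j] = open_
            ptr_e[0, j] = 0
        else:
            E[0, j] = ext
            ptr_e[0, j] = 1
        H[0, j] = E[0, j]
        ptr_h[0, j] = 3
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            open_ = H[i, j - 1] - go
            ext = E[i, j - 1] - gap_extend
            if open_ >= ext:
                E[i, j] = open_
                ptr_e[i, j] = 0
            else:
                E[i, j] = ext
                ptr_e[i, j] = 1
            open_ = H[i - 1, j] - go
            ext = F[i - 1, j] - gap_extend
            if open_ >= ext:
                F[i, j] = open_
                ptr_f[i, j] = 0
            else:
                F[i, j] = ext
                ptr_f[i, j] = 1
            diag = H[i - 1, j - 1] + C[i - 1, j - 1]
            best = diag
            move = 1
            if F[i, j] > best:
                best = F[i, j]
                move = 2
            if E[i, j] > best:
                best = E[i, j]
                move = 3
            H[i, j] = best
            ptr_h[i, j] = move
    # traceback through the three-state graph
    moves = np.empty(la + lb, dtype=np.uint8)
    k = 0
    i, j = la, lb
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 or j > 0:
        if state == 0:
            mv = ptr_h[i, j]
            if mv == 1:
                moves[k] = 1
                k += 1
                i -= 1
                j -= 1
            elif mv == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            moves[k] = 3
            k += 1
            if ptr_e[i, j] == 0:
                state = 0
            j -= 1
        else:
            moves[k] = 2
            k += 1
            if ptr_f[i, j] == 0:
                state = 0
            i -= 1
    return H[la, lb], moves[:k]


def _merge(rows_a: list[str], rows_b: list[str], S: np.ndarray, p: ScoringParams):
    """Align two sub-alignments and return the merged rows (A's rows first)."""
    prof_a = _profile(rows_a)
    prof_b = _profile(rows_b)
    C = (prof_a @ S) @ prof_b.T
    score, moves = _align_profiles(C, float(p.gap_open), float(p.gap_extend))
    la = len(rows_a[0])
    lb = len(rows_b[0])
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for mv in moves[::-1]:
        if mv == 1:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            i += 1
            j += 1
        elif mv == 2:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r in range(len(rows_b)):
                out_b[r].append("-")
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append("-")
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            j += 1
    assert i == la and j == lb
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b], score


def pairwise_global_score(a: str, b: str, p: ScoringParams = ScoringParams()) -> float:
    """Optimal global affine-gap alignment score of two sequences (the
    2-sequence specialization of the profile aligner)."""
    S = _substitution_matrix(p)
    pa = _profile([a])
    pb = _profile([b])
    C = (pa @ S) @ pb.T
    score, _ = _align_profiles(C, float(p.gap_open), float(p.gap_extend))
    return float(score)


def progressive_align(
    sequences: Sequence[tuple[str, str]],
    p: ScoringParams = ScoringParams(),
) -> Msa:
    """Align a group given as ``(id, residues)`` pairs.

    The guide tree is neighbor joining on k-mer profile distances; profiles
    are merged in postorder.  A single sequence round-trips unchanged.
    """
    from .gene_trees import nj  # deferred: gene_trees consumes Msa
    from .homolog_grouping import DistanceMatrix

    sequences = list(sequences)
    ids = [s[0] for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in group")
    seqs = dict(sequences)
    if len(sequences) == 0:
        raise ValueError("empty group")
    S = _substitution_matrix(p)
    if len(sequences) == 1:
        return Msa(ids=list(ids), rows=[sequences[0][1]])
    if len(sequences) == 2:
        ra, rb, _ = _merge([sequences[0][1]], [sequences[1][1]], S, p)
        return Msa(ids=list(ids), rows=ra + rb)
    order = sorted(ids)
    n = len(order)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_profile_distance(seqs[order[i]], seqs[order[j]])
    guide = nj(DistanceMatrix(ids=order, d=d))

    def merge_clade(node):
        if node.is_leaf:
            return [node.label], [seqs[node.label]]
        child_results = [merge_clade(c) for c in node.children]
        acc_ids, acc_rows = child_results[0]
        for cid, crows in child_results[1:]:
            acc_rows, brows, _ = _merge(acc_rows, crows, S, p)
            acc_ids = acc_ids + cid
            acc_rows = acc_rows + brows
        return acc_ids, acc_rows

    aligned_ids, aligned_rows = merge_clade(guide.root)
    # restore input row order
    row_of = dict(zip(aligned_ids, aligned_rows))
    return Msa(ids=list(ids), rows=[row_of[i] for i in ids])


def write_msa_fasta(msa: Msa, path) -> None:
    write_fasta(
        (SeqRecord(id=i, residues=r) for i, r in zip(msa.ids, msa.rows)),
        path,
    )
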