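"""All-vs-all nucleotide similarity search.

Homolog grouping needs, for every ordered pair of candidate genes, the best
local-alignment score and an E-value to threshold on.  This module provides
that with a classic seed-and-extend design: an exact k-mer index proposes
candidate subjects, each candidate is scored by banded Smith-Waterman
(affine gaps) around the best seed diagonal, and significance is assessed
with Karlin-Altschul statistics

    E = K * m * n * exp(-lambda * S),    bits = (lambda * S - ln K) / ln 2

where ``S`` is the raw score, ``m`` the query length and ``n`` the total
database length.  Default scoring constants are BLASTN-like
(match +2, mismatch -3, gap open 5, gap extend 2, lambda 0.625, K 0.41,
word size 11); only the threshold ordering of pairs matters downstream, so
effective-length corrections are deliberately omitted.  The default
E-value cutoff is 1e-20 and, like the scoring constants, is exposed in the
run configuration so it can be raised for distantly related inputs or
lowered for close ones.

The module is a pure function of its inputs: no randomness anywhere, ties
on seed count broken toward the smallest diagonal index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .formats_io import GeneSeq

_NEG = -(10**9)

_ENCODE = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))


def encode(residues: str) -> np.ndarray:
    """Map residues to integer codes A=0 C=1 G=2 T=3 N=4."""
    return np.frombuffer(residues.encode().translate(_ENCODE), dtype=np.uint8)


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring and statistics parameters (BLASTN-like defaults)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    ka_lambda: float = 0.625
    ka_k: float = 0.41
    word_k: int = 11
    band_halfwidth: int = 32

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.word_k < 4:
            raise ValueError("word_k must be >= 4")


@dataclass(frozen=True)
class Hit:
    """Best local alignment between an ordered pair of genes."""

    query_id: str
    subject_id: str
    raw_score: int
    bitscore: float
    evalue: float
    query_span: tuple[int, int]  # 0-based half-open
    subject_span: tuple[int, int]


# ---------------------------------------------------------------------------
# Smith-Waterman (Gotoh affine gaps), full and banded
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_best_end(a, b, match, mismatch, gap_open, gap_extend, d0, w, banded):
    """Best local score and its end cell; optionally restricted to the band
    |(j - i) - d0| <= w.  Opening a gap costs gap_open + gap_extend."""
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n + 1, _NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, m + 1):
        if banded:
            jlo = i + d0 - w
            if jlo < 1:
                jlo = 1
            jhi = i + d0 + w
            if jhi > n:
                jhi = n
            if jlo > n or jhi < 1:
                continue
            if jhi == i + d0 + w:
                # cell above the band's right edge was never written this
                # diagonal sweep; treat it as outside (score 0, no open gap)
                H[jhi] = 0
                F[jhi] = _NEG
        else:
            jlo = 1
            jhi = n
        hdiag = H[jlo - 1]
        hleft = 0
        e = _NEG
        ai = a[i - 1]
        for j in range(jlo, jhi + 1):
            bjc = b[j - 1]
            if ai >= 4 or bjc >= 4:
                sc = 0
            elif ai == bjc:
                sc = match
            else:
                sc = mismatch
            ecand = hleft - go
            e = e - gap_extend
            if ecand > e:
                e = ecand
            fcand = H[j] - go
            f = F[j] - gap_extend
            if fcand > f:
                f = fcand
            F[j] = f
            h = hdiag + sc
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            hdiag = H[j]
            H[j] = h
            hleft = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


def smith_waterman(
    a: str, b: str, p: ScoringParams = ScoringParams()
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Optimal local alignment score with one optimal span pair.

    Returns ``(raw_score, (a_start, a_end), (b_start, b_end))`` with
    0-based half-open spans; score 0 (empty spans) when no positive-scoring
    alignment exists, including for empty input.
    """
    return _sw_span(encode(a), encode(b), p, banded=False, d0=0)


def banded_smith_waterman(
    a: str, b: str, p: ScoringParams, diagonal: int
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Smith-Waterman restricted to a diagonal band of half-width
    ``p.band_halfwidth`` around ``diagonal`` (= b_offset - a_offset)."""
    return _sw_span(encode(a), encode(b), p, banded=True, d0=diagonal)


def _sw_span(ea, eb, p: ScoringParams, banded: bool, d0: int):
    if len(ea) == 0 or len(eb) == 0:
        return 0, (0, 0), (0, 0)
    score, bi, bj = _sw_best_end(
        ea, eb, p.match, p.mismatch, p.gap_open, p.gap_extend,
        d0, p.band_halfwidth, banded,
    )
    if score == 0:
        return 0, (0, 0), (0, 0)
    # locate the alignment start by solving the reversed prefix problem:
    # the same best score ends at the start cell's reflection
    ra = ea[:bi][::-1].copy()
    rb = eb[:bj][::-1].copy()
    rd0 = (len(rb) - len(ra)) - d0 if banded else 0
    _, ri, rj = _sw_best_end(
        ra, rb, p.match, p.mismatch, p.gap_open, p.gap_extend,
        rd0, p.band_halfwidth, banded,
    )
    return score, (bi - ri, bi), (bj - rj, bj)


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def evalue(raw_score: int, m: int, n: int, p: ScoringParams = ScoringParams()) -> float:
    """Expected number of chance alignments scoring >= raw_score between a
    query of length m and a database of total length n."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return p.ka_k * m * n * math.exp(-p.ka_lambda * raw_score)


def bitscore(raw_score: int, p: ScoringParams = ScoringParams()) -> float:
    return (p.ka_lambda * raw_score - math.log(p.ka_k)) / math.log(2.0)


# ---------------------------------------------------------------------------
# seeded search
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact k-mer postings over a gene set (the in-memory 'database')."""

    def __init__(self, genes: Sequence[GeneSeq], word_k: int) -> None:
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_id in input: {dupes}")
        self.word_k = word_k
        self.genes = list(genes)
        self.ids = ids
        self.encoded = [encode(g.residues) for g in genes]
        self.total_length = sum(len(g.residues) for g in genes)
        self.postings: dict[str, list[tuple[int, int]]] = {}
        for gi, g in enumerate(genes):
            s = g.residues
            for off in range(len(s) - word_k + 1):
                word = s[off : off + word_k]
                if "N" in word:
                    continue
                self.postings.setdefault(word, []).append((gi, off))


def seeded_search(
    query: GeneSeq,
    index: SeedIndex,
    p: ScoringParams = ScoringParams(),
    e_threshold: float = 1e-20,
) -> list[Hit]:
    """Hits of one query against the index, best hit per subject, filtered
    at ``evalue <= e_threshold``.  Self-matches are skipped."""
    k = index.word_k
    q = query.residues
    # (subject, diagonal) -> seed count
    diag_counts: dict[tuple[int, int], int] = {}
    for off in range(len(q) - k + 1):
        word = q[off : off + k]
        if "N" in word:
            continue
        for gi, soff in index.postings.get(word, ()):
            if index.ids[gi] == query.gene_id:
                continue
            key = (gi, soff - off)
            diag_counts[key] = diag_counts.get(key, 0) + 1
    if not diag_counts:
        return []
    # best diagonal per candidate subject: max seed count, then smallest diag
    best_diag: dict[int, tuple[int, int]] = {}
    for (gi, diag), count in sorted(diag_counts.items()):
        cur = best_diag.get(gi)
        if cur is None or count > cur[0]:
            best_diag[gi] = (count, diag)
    eq = encode(q)
    hits: list[Hit] = []
    for gi in sorted(best_diag):
        _, diag = best_diag[gi]
        score, qspan, sspan = _sw_span(eq, index.encoded[gi], p, banded=True, d0=diag)
        if score <= 0:
            continue
        e = evalue(score, len(q), index.total_length, p)
        if e <= e_threshold:
            hits.append(
                Hit(
                    query_id=query.gene_id,
                    subject_id=index.ids[gi],
                    raw_score=score,
                    bitscore=bitscore(score, p),
                    evalue=e,
                    query_span=qspan,
                    subject_span=sspan,
                )
            )
    hits.sort(key=lambda h: h.subject_id)
    return hits


def all_vs_all(
    genes: Sequence[GeneSeq],
    p: ScoringParams = ScoringParams(),
    e_threshold: float = 1e-20,
    batch_size: int = 50,
    mapper: Optional[Callable] = None,
) -> list[Hit]:
    """Every gene queried against the index over all genes.

    Queries are processed in batches of ``batch_size`` (default 50,
    mirroring the search batching of the original pipeline) through
    ``mapper`` (the deterministic parallel-map contract; serial map when
    None).  Output is order-normalized by (query_id, subject_id) and is
    identical regardless of worker count.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    index = SeedIndex(genes, p.word_k)  # raises on duplicate gene_id
    batches = [list(genes[i : i + batch_size]) for i in range(0, len(genes), batch_size)]

    def run_batch(batch: list[GeneSeq]) -> list[Hit]:
        out: list[Hit] = []
        for g in batch:
            out.extend(seeded_search(g, index, p, e_threshold))
        return out

    if mapper is None:
        results = [run_batch(b) for b in batches]
    else:
        results = mapper(_BatchRunner(index, p, e_threshold), batches)
    hits = [h for batch in results for h in batch]
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


class _BatchRunner:
    """Picklable batch worker for process-based parallel maps."""

    def __init__(self, index: SeedIndex, p: ScoringParams, e_threshold: float):
        self.index = index
        self.p = p
        self.e_threshold = e_threshold

    def __call__(self, batch: list[GeneSeq]) -> list[Hit]:
        out: list[Hit] = []
        for g in batch:
            out.extend(seeded_search(g, self.index, self.p, self.e_threshold))
        return out


# ---------------------------------------------------------------------------
# TSV interchange (BLAST outfmt-6 column order)
# ---------------------------------------------------------------------------

def write_hits_tsv(hits: Iterable[Hit], path) -> None:
    """Dump hits in BLAST outfmt-6 column order (pident/mismatch/gapopen
    are placeholders: this engine does not report them)."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_span
            ss, se = h.subject_span
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0.0\t{qe - qs}\t0\t0\t"
                f"{qs + 1}\t{qe}\t{ss + 1}\t{se}\t{h.evalue:.3g}\t{h.bitscore:.2f}\n"
            )


def read_hits_tsv(path, p: ScoringParams = ScoringParams()) -> list[Hit]:
    """Read an outfmt-6 table (ours, or real BLAST output used as a drop-in
    backend).  Raw scores are recovered from the bitscore by inverting the
    Karlin-Altschul relation."""
    hits: list[Hit] = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise ValueError(f"{path}: expected 12 outfmt-6 columns")
            q, s = cols[0], cols[1]
            qs, qe, ss, se = (int(cols[i]) for i in (6, 7, 8, 9))
            e, bits = float(cols[10]), float(cols[11])
            raw = round((bits * math.log(2.0) + math.log(p.ka_k)) / p.ka_lambda)
            hits.append(Hit(q, s, raw, bits, e, (qs - 1, qe), (ss - 1, se)))
    return hits
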