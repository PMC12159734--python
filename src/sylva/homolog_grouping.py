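"""From a hit table to homolog groups.

This is the clustering heart of the pipeline: pairwise similarity evidence
becomes a distance matrix, DBSCAN finds dense clusters (putative homolog
families) without fixing their number or size, clusters outside the
configured size window are dropped, and a random subset of the survivors is
sampled for gene-tree building.

The distance between genes i and j is defined from the best raw alignment
score in either direction, normalized by the smaller self-alignment score:

    s(i,j) = best_raw(i,j) / min(self(i), self(j)),  clamped to [0,1]
    d(i,j) = 1 - s(i,j)       (d = 1 when no hit passes the E-value cutoff)

which is bounded in [0,1], symmetric, and zero exactly for sequences that
align end-to-end as well as they align to themselves.

DBSCAN here is the textbook algorithm made fully deterministic: ids are
scanned in lexicographic order, core points (>= min_pts neighbors within
eps, self included) chain into clusters as connected components, border
points join the cluster of their first core neighbor in scan order, and
cluster indices follow the first core point encountered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats_io import GeneSeq, species_of
from .similarity_search import Hit, ScoringParams, smith_waterman

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass(frozen=True)
class GroupingParams:
    """Knobs for distance construction, clustering and sampling.

    ``dbscan_min_pts`` defaults to ``min_group_size``: a cluster below the
    size filter could never survive anyway.
    """

    e_threshold: float = 1e-20
    dbscan_eps: float = 0.7
    dbscan_min_pts: Optional[int] = None  # None -> min_group_size
    min_group_size: int = 3
    max_group_size: int = 100
    max_gene_trees: int = 50
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 < self.dbscan_eps <= 1):
            raise ValueError("dbscan_eps must be in (0, 1]")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        if self.max_group_size < self.min_group_size:
            raise ValueError("max_group_size must be >= min_group_size")

    @property
    def min_pts(self) -> int:
        return self.dbscan_min_pts if self.dbscan_min_pts is not None else self.min_group_size


@dataclass
class DistanceMatrix:
    """Symmetric gene-gene distances in [0,1] with zero diagonal."""

    ids: list[str]
    d: np.ndarray  # shape (n, n), float64

    def index_of(self, gene_id: str) -> int:
        return self.ids.index(gene_id)


@dataclass
class SeqGroup:
    """A putative homolog family."""

    group_id: int
    members: list[str]  # gene_ids, sorted
    species_cover: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.species_cover:
            self.species_cover = {species_of(g) for g in self.members}


def self_scores(genes: Sequence[GeneSeq], p: ScoringParams = ScoringParams()) -> dict[str, int]:
    """Self-alignment raw score per gene (the normalization denominator).

    For an ungapped self alignment this is just match * length, but the
    general path is kept so alternative scoring schemes stay correct.
    """
    out: dict[str, int] = {}
    for g in genes:
        if "N" in g.residues:
            out[g.gene_id], _, _ = smith_waterman(g.residues, g.residues, p)
        else:
            out[g.gene_id] = p.match * len(g.residues)
    return out


def build_distance_matrix(
    hits: Sequence[Hit],
    genes: Sequence[GeneSeq],
    params: GroupingParams,
    self_raw: Optional[dict[str, int]] = None,
    p: ScoringParams = ScoringParams(),
) -> DistanceMatrix:
    """Distance matrix from the hit table (see module docstring for the
    definition).  Hits above the E-value threshold are ignored; a hit that
    references a gene absent from ``genes`` is an error."""
    ids = sorted(g.gene_id for g in genes)
    idx = {g: i for i, g in enumerate(ids)}
    if self_raw is None:
        self_raw = self_scores(genes, p)
    n = len(ids)
    d = np.ones((n, n), dtype=np.float64)
    np.fill_diagonal(d, 0.0)
    best: dict[tuple[int, int], int] = {}
    for h in hits:
        if h.query_id not in idx or h.subject_id not in idx:
            missing = h.query_id if h.query_id not in idx else h.subject_id
            raise ValueError(f"hit references unknown gene_id {missing!r}")
        if h.evalue > params.e_threshold:
            continue
        i, j = idx[h.query_id], idx[h.subject_id]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if h.raw_score > best.get(key, 0):
            best[key] = h.raw_score
    for (i, j), raw in best.items():
        denom = min(self_raw[ids[i]], self_raw[ids[j]])
        s = min(1.0, max(0.0, raw / denom)) if denom > 0 else 0.0
        d[i, j] = d[j, i] = 1.0 - s
    return DistanceMatrix(ids=ids, d=d)


def dbscan(D: DistanceMatrix, eps: float, min_pts: int) -> dict[str, int]:
    """Deterministic DBSCAN over a precomputed distance matrix.

    Returns a label per id: a cluster index >= 0 or ``NOISE`` (-1).
    """
    if not (0 < eps <= 1):
        raise ValueError("eps must be in (0, 1]")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    order = sorted(range(len(D.ids)), key=lambda i: D.ids[i])
    neighbors = D.d <= eps  # self included (diagonal is 0)
    degree = neighbors.sum(axis=1)
    is_core = degree >= min_pts

    labels = {i: NOISE for i in range(len(D.ids))}
    cluster = -1
    # clusters = connected components of core points under the eps relation,
    # discovered in lexicographic id order so indices are reproducible
    for i in order:
        if not is_core[i] or labels[i] != NOISE:
            continue
        cluster += 1
        stack = [i]
        labels[i] = cluster
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(neighbors[u]):
                v = int(v)
                if is_core[v] and labels[v] == NOISE:
                    labels[v] = cluster
                    stack.append(v)
    # border points: first core neighbor in scan order decides the cluster
    for i in order:
        if is_core[i] or labels[i] != NOISE:
            continue
        for j in order:
            if j != i and neighbors[i][j] and is_core[j]:
                labels[i] = labels[j]
                break
    return {D.ids[i]: lab for i, lab in labels.items()}


def filter_groups(labels: dict[str, int], params: GroupingParams) -> list[SeqGroup]:
    """Drop noise and clusters outside [min_group_size, max_group_size];
    survivors become SeqGroups ordered by cluster index."""
    clusters: dict[int, list[str]] = {}
    for gid, lab in labels.items():
        if lab == NOISE:
            continue
        clusters.setdefault(lab, []).append(gid)
    groups: list[SeqGroup] = []
    for lab in sorted(clusters):
        members = sorted(clusters[lab])
        if params.min_group_size <= len(members) <= params.max_group_size:
            groups.append(SeqGroup(group_id=lab, members=members))
        else:
            logger.debug("cluster %d dropped (size %d)", lab, len(members))
    return groups


def sample_groups(
    groups: Sequence[SeqGroup], max_gene_trees: int, seed: int
) -> list[SeqGroup]:
    """Uniform random subset of at most ``max_gene_trees`` groups,
    reproducible for a fixed seed; all groups (stable order) when there are
    no more than the maximum."""
    groups = list(groups)
    if len(groups) <= max_gene_trees:
        return groups
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(groups), size=max_gene_trees, replace=False)
    return [groups[i] for i in sorted(chosen)]


def write_groups_tsv(groups: Sequence[SeqGroup], path) -> None:
    """One line per group: tab-separated member gene ids."""
    with open(path, "w") as fh:
        for g in groups:
            fh.write("\t".join(g.members) + "\n")
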