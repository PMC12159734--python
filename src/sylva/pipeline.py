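"""End-to-end orchestration: inputs to annotated species tree.

Stages run in a fixed order — identify gene sequences, all-vs-all
similarity search, distance matrix, DBSCAN, size filtering, group
sampling, alignment, gene trees, quartet tally, tree search, branch
annotation — with per-stage on-disk caching keyed by a hash of the
configuration and the input files, so a rerun recomputes only what
changed.

Per species the gene-identification mode follows the priority
coding sequences > annotation > ORF prediction; different species may use
different modes in one run.  Species that end up in no sampled group
cannot be placed in the tree: they are omitted with a warning and listed
in ``omitted_species.txt``.

Randomness (group sampling, quartet subsampling, heuristic search) is
pinned by the configured seed, so a run is bit-identical for a fixed
configuration and seed regardless of the worker count; pass a fresh seed
per run to explore the sampling variability instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import yaml

from . import gene_trees as gene_trees_mod
from . import homolog_grouping as grouping
from . import msa as msa_mod
from . import orf_finder
from . import similarity_search as sim
from . import species_tree as sptree
from .formats_io import (
    GeneSeq,
    Tree,
    extract_cds_from_gff3,
    make_gene_id,
    parse_newick,
    read_fasta,
    write_newick,
)
from .species_tree import SpeciesTreeResult

logger = logging.getLogger(__name__)

DEFAULT_BATCH_SIZE = 50  # queries per similarity-search task


@dataclass
class SpeciesInput:
    """Declared input files for one species; mode is derived from the
    files present with priority cds > gff3 > genome."""

    species_id: str
    cds: Optional[str] = None
    gff3: Optional[str] = None
    genome: Optional[str] = None

    @property
    def mode(self) -> str:
        if self.cds:
            return "cds"
        if self.gff3:
            return "gff3"
        if self.genome:
            return "genome"
        raise ValueError(f"species {self.species_id}: no input file declared")


@dataclass
class PipelineConfig:
    species: list[SpeciesInput] = field(default_factory=list)
    e_threshold: float = 1e-20
    min_group_size: int = 3
    max_group_size: int = 100
    max_gene_trees: int = 50
    dbscan_eps: float = 0.7
    min_orf_len: int = 300
    seed: int = 42
    workers: int = 1
    exact_limit: int = 8
    batch_size: int = DEFAULT_BATCH_SIZE
    output_dir: str = "sylva_out"
    keep_intermediates: bool = False
    scoring: sim.ScoringParams = field(default_factory=sim.ScoringParams)

    def __post_init__(self) -> None:
        # validate thresholds eagerly through the stage parameter objects
        self.grouping_params()
        if self.min_orf_len < 6 or self.min_orf_len % 3:
            raise ValueError("min_orf_len must be >= 6 and divisible by 3")
        if self.workers < 1 or self.batch_size < 1:
            raise ValueError("workers and batch_size must be >= 1")

    def grouping_params(self) -> grouping.GroupingParams:
        return grouping.GroupingParams(
            e_threshold=self.e_threshold,
            dbscan_eps=self.dbscan_eps,
            min_group_size=self.min_group_size,
            max_group_size=self.max_group_size,
            max_gene_trees=self.max_gene_trees,
            seed=self.seed,
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML run configuration (keys mirror PipelineConfig)."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, base_dir=path.parent)

def config_from_dict(raw: dict, base_dir: Optional[Path] = None) -> PipelineConfig:
    def respath(p):
        if p is None:
            return None
        p = Path(p)
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        return str(p)

    species = [
        SpeciesInput(
            species_id=str(s["id"]),
            cds=respath(s.get("cds")),
            gff3=respath(s.get("gff3")),
            genome=respath(s.get("genome")),
        )
        for s in raw.get("species", [])
    ]
    scoring_raw = raw.get("scoring", {})
    kwargs = {
        k: raw[k]
        for k in (
            "e_threshold", "min_group_size", "max_group_size", "max_gene_trees",
            "dbscan_eps", "min_orf_len", "seed", "workers", "exact_limit",
            "batch_size", "keep_intermediates",
        )
        if k in raw
    }
    if "e_threshold" in kwargs:
        kwargs["e_threshold"] = float(kwargs["e_threshold"])
    if "output_dir" in raw:
        kwargs["output_dir"] = respath(raw["output_dir"])
    return PipelineConfig(
        species=species, scoring=sim.ScoringParams(**scoring_raw), **kwargs
    )


# ---------------------------------------------------------------------------
# deterministic parallel map
# ---------------------------------------------------------------------------

def parallel_map(fn: Callable, items: Sequence, workers: int = 1) -> list:
    """Apply a pure function to every item, in input order, with results
    independent of the worker count.  A worker failure fails the whole
    stage with the offending item's index."""
    items = list(items)
    if not items:
        return []
    if workers <= 1:
        results = []
        for i, item in enumerate(items):
            try:
                results.append(fn(item))
            except Exception as exc:
                raise RuntimeError(f"stage task {i} failed: {exc}") from exc
        return results
    with ProcessPoolExecutor(max_workers=workers) as pool:
        futures = [pool.submit(fn, item) for item in items]
        results = []
        for i, fut in enumerate(futures):
            try:
                results.append(fut.result())
            except Exception as exc:
                raise RuntimeError(f"stage task {i} failed: {exc}") from exc
        return results


# ---------------------------------------------------------------------------
# stage cache
# ---------------------------------------------------------------------------

def _sha(parts: Sequence[str]) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\0")
    return h.hexdigest()


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageCache:
    """Pickle-per-stage cache keyed on upstream content hashes."""

    def __init__(self, directory: Path, enabled: bool = True) -> None:
        self.directory = directory
        self.enabled = enabled
        if enabled:
            directory.mkdir(parents=True, exist_ok=True)

    def get_or_compute(self, stage: str, key: str, compute: Callable[[], object]):
        path = self.directory / f"{stage}-{key[:20]}.pkl"
        if self.enabled and path.exists():
            logger.info("stage %s: reusing cached result", stage)
            with path.open("rb") as fh:
                return pickle.load(fh)
        logger.info("stage %s: computing", stage)
        value = compute()
        if self.enabled:
            with path.open("wb") as fh:
                pickle.dump(value, fh)
        return value


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def resolve_inputs(config: PipelineConfig) -> dict[str, list[GeneSeq]]:
    """Gene sequences per species, honoring the mode priority
    cds > annotation > orf."""
    out: dict[str, list[GeneSeq]] = {}
    for spec in config.species:
        sp = spec.species_id
        if spec.cds and spec.gff3:
            logger.warning(
                "species %s: both cds and gff3 declared; using cds", sp
            )
        try:
            if spec.cds:
                records = read_fasta(spec.cds, species_id=sp)
                genes = [
                    GeneSeq(
                        species_id=sp,
                        gene_id=make_gene_id(sp, rec.id),
                        residues=rec.residues,
                        origin="cds",
                    )
                    for rec in records
                ]
            elif spec.gff3:
                if not spec.genome:
                    raise ValueError("gff3 declared without a genome FASTA")
                genome = read_fasta(spec.genome, species_id=sp)
                genes = extract_cds_from_gff3(spec.gff3, genome, species_id=sp)
            else:
                genome = read_fasta(spec.genome, species_id=sp)
                genes = orf_finder.orfs_to_genes(sp, genome, config.min_orf_len)
        except OSError as exc:
            raise RuntimeError(f"species {sp}: cannot read input ({exc})") from exc
        logger.info("species %s: %d gene sequences (%s)", sp, len(genes), spec.mode)
        out[sp] = genes
    return out


def _align_and_tree(task) -> tuple[int, "msa_mod.Msa", Optional[str]]:
    """Per-group worker: progressive alignment then NJ gene tree."""
    group_id, members = task
    aln = msa_mod.progressive_align(members)
    tree = gene_trees_mod.build_gene_tree(aln)
    return group_id, aln, write_newick(tree) if tree is not None else None


def run_pipeline(config: PipelineConfig) -> SpeciesTreeResult:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="a")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root_logger = logging.getLogger("sylva")
    root_logger.addHandler(log_handler)
    try:
        return _run(config, out_dir)
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()


def _config_fingerprint(config: PipelineConfig) -> dict:
    d = asdict(config)
    d.pop("output_dir")
    d.pop("keep_intermediates")
    d.pop("workers")  # never affects results
    return d


def _run(config: PipelineConfig, out_dir: Path) -> SpeciesTreeResult:
    if len(config.species) < 4:
        raise RuntimeError("need at least 4 input species: no quartets exist")
    cache = StageCache(out_dir / ".cache")
    cfg_json = json.dumps(_config_fingerprint(config), sort_keys=True, default=str)
    input_hashes = []
    for spec in config.species:
        for path in (spec.cds, spec.gff3, spec.genome):
            if path:
                input_hashes.append(_file_hash(path))
    genes_key = _sha([cfg_json, "genes", *input_hashes])
    genes_by_species = cache.get_or_compute(
        "genes", genes_key, lambda: resolve_inputs(config)
    )
    empty = [sp for sp, genes in genes_by_species.items() if not genes]
    if empty:
        raise RuntimeError(f"no gene sequences identified for species: {empty}")
    all_genes = [g for sp in sorted(genes_by_species) for g in genes_by_species[sp]]
    logger.info("total gene sequences: %d", len(all_genes))

    hits_key = _sha([genes_key, "hits"])
    hits = cache.get_or_compute(
        "similarity",
        hits_key,
        lambda: sim.all_vs_all(
            all_genes,
            config.scoring,
            config.e_threshold,
            batch_size=config.batch_size,
            mapper=lambda fn, batches: parallel_map(fn, batches, config.workers),
        ),
    )
    logger.info("similarity search: %d hits", len(hits))
    if config.keep_intermediates:
        sim.write_hits_tsv(hits, out_dir / "hits.tsv")

    gparams = config.grouping_params()
    groups_key = _sha([hits_key, "groups"])

    def make_groups():
        D = grouping.build_distance_matrix(hits, all_genes, gparams, p=config.scoring)
        labels = grouping.dbscan(D, gparams.dbscan_eps, gparams.min_pts)
        return grouping.filter_groups(labels, gparams)

    groups = cache.get_or_compute("grouping", groups_key, make_groups)
    if not groups:
        raise RuntimeError(
            "no sequence groups survived clustering and size filtering; "
            "consider raising e_threshold for distantly related inputs"
        )
    sampled = grouping.sample_groups(groups, config.max_gene_trees, config.seed)
    logger.info("groups: %d found, %d sampled", len(groups), len(sampled))
    grouping.write_groups_tsv(sampled, out_dir / "groups.tsv")

    residues = {g.gene_id: g.residues for g in all_genes}
    tasks = [
        (g.group_id, [(m, residues[m]) for m in g.members]) for g in sampled
    ]
    trees_key = _sha([groups_key, "genetrees", str(config.seed)])
    results = cache.get_or_compute(
        "gene_trees",
        trees_key,
        lambda: parallel_map(_align_and_tree, tasks, config.workers),
    )
    aln_dir = out_dir / "alignments"
    tree_dir = out_dir / "gene_trees"
    aln_dir.mkdir(exist_ok=True)
    tree_dir.mkdir(exist_ok=True)
    gene_tree_list: list[Tree] = []
    for group_id, aln, nwk in results:
        msa_mod.write_msa_fasta(aln, aln_dir / f"group{group_id:05d}.fasta")
        if nwk is not None:
            (tree_dir / f"group{group_id:05d}.nwk").write_text(nwk + "\n")
            gene_tree_list.append(parse_newick(nwk))
    logger.info("gene trees built: %d", len(gene_tree_list))

    all_species = sorted({s.species_id for s in config.species})
    tally = sptree.tally_quartets(gene_tree_list, seed=config.seed)
    placed = tally.species
    omitted = sorted(set(all_species) - set(placed))
    if omitted:
        logger.warning(
            "species absent from every sampled group, omitted from the tree: %s",
            ", ".join(omitted),
        )
    (out_dir / "omitted_species.txt").write_text(
        "".join(sp + "\n" for sp in omitted)
    )
    if len(placed) < 4:
        raise RuntimeError(
            f"only {len(placed)} species carry grouped genes: no quartets exist"
        )
    if len(placed) <= config.exact_limit:
        best = sptree.exact_search(tally, placed, config.exact_limit)
    else:
        best = sptree.heuristic_search(tally, placed, seed=config.seed)
    result = sptree.annotate_branches(best, tally, omitted_species=omitted)
    (out_dir / "species_tree.nwk").write_text(write_newick(result.tree) + "\n")
    logger.info("species tree written: %s", out_dir / "species_tree.nwk")
    return result
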