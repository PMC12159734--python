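"""Synthetic study systems with known ground truth.

Every stage of the pipeline — and the end-to-end recovery tests — runs on
data generated here: a pure-birth (Yule) species tree of height 1, gene
families evolved along it under Jukes-Cantor substitution, and emission in
any of the three input modes the pipeline accepts (provided coding
sequences, genome + GFF3 annotation, or bare genome).  A family is an
ATG-initiated, TAA-terminated open reading frame with no internal in-frame
stop, so ORF finding can recover it exactly from genome mode.

Genomes are assembled by alternating genes (random strand) with spacers
built from the 4-mer ``TTAA`` repeated: that motif contains a stop codon
in every reading frame on both strands and no ATG, so planted ORFs
dominate the six-frame scan and no spurious ORF can bridge two genes.

With probability ``dup_prob`` a family carries a second, independently
evolved copy in one random species, exercising the multicopy path of the
species-tree stage.  Gene loss is not simulated; the omission path is
tested by planting an unrelated random genome (``random_genome``).

Everything is deterministic given the seed (numpy PCG64 generators keyed
on (seed, stream constants)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import SeqRecord, Tree, TreeNode, write_fasta, write_newick
from .orf_finder import STOP_CODONS, reverse_complement

_BASES = "ACGT"
SPACER_MOTIF = "TTAA"  # stop in all six frames, no ATG, self-reverse-complement

_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_SAFE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic system."""

    n_species: int = 8
    n_families: int = 40
    gene_length: int = 600  # nt, divisible by 3, includes start+stop codons
    sub_rate: float = 0.1  # expected substitutions/site over tree height 1
    dup_prob: float = 0.1  # per-family chance of one extra copy
    spacer_length: int = 200  # nt between planted genes
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if self.gene_length % 3 or self.gene_length < 9:
            raise ValueError("gene_length must be >= 9 and divisible by 3")
        if min(self.n_families, self.sub_rate, self.dup_prob + 1,
               self.spacer_length) < 0:
            raise ValueError("parameters must be non-negative")


def species_label(i: int) -> str:
    return f"s{i:02d}"


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(n_species: int, seed: int) -> Tree:
    """Yule tree: uniformly chosen pending lineage splits after an
    exponential waiting time; branch lengths normalized to total height 1.
    Leaves are labeled s00, s01, ... in creation order."""
    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = np.random.default_rng([seed, 101])
    root = TreeNode()
    c1, c2 = TreeNode(), TreeNode()
    root.add(c1)
    root.add(c2)
    active: list[tuple[TreeNode, float]] = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.length = t - birth
        a, b = TreeNode(), TreeNode()
        node.add(a)
        node.add(b)
        active.append((a, t))
        active.append((b, t))
    t_end = t + rng.exponential(1.0 / n_species)
    for i, (node, birth) in enumerate(active):
        node.label = species_label(i)
        node.length = t_end - birth
    # normalize to height exactly 1
    for node in root.walk():
        if node.length is not None:
            node.length /= t_end
    return Tree(root, rooted=True)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _random_orf(rng: np.random.Generator, length: int) -> str:
    n_mid = length // 3 - 2
    mid = "".join(_SAFE_CODONS[int(i)] for i in rng.integers(len(_SAFE_CODONS), size=n_mid))
    return "ATG" + mid + "TAA"


def _mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    """Jukes-Cantor step: each internal site substituted with probability p
    (uniform over the other three bases); the start and stop codons are
    held fixed and internal in-frame stops are re-rolled."""
    if p <= 0:
        return seq
    arr = list(seq)
    n = len(arr)
    hits = np.flatnonzero(rng.random(n) < p)
    for i in hits:
        if i < 3 or i >= n - 3:
            continue  # protect start/stop codons
        cur = arr[i]
        alt = [b for b in _BASES if b != cur]
        arr[i] = alt[int(rng.integers(3))]
    # repair any internal in-frame stop created by the substitutions
    for c in range(3, n - 3, 3):
        if "".join(arr[c : c + 3]) in STOP_CODONS:
            arr[c : c + 3] = _SAFE_CODONS[int(rng.integers(len(_SAFE_CODONS)))]
    return "".join(arr)


def _evolve_down(node: TreeNode, seq: str, sub_rate: float,
                 rng: np.random.Generator, out: dict[str, str]) -> None:
    for child in node.children:
        p = (child.length or 0.0) * sub_rate
        child_seq = _mutate(seq, p, rng)
        if child.is_leaf:
            out[child.label] = child_seq
        else:
            _evolve_down(child, child_seq, sub_rate, rng, out)


def evolve_family(
    species_tree: Tree,
    params: SimulationParams,
    family_index: int,
) -> dict[str, list[str]]:
    """One gene family: per species a list of 1 or 2 evolved copies."""
    rng = np.random.default_rng([params.seed, 211, family_index])
    root_seq = _random_orf(rng, params.gene_length)
    primary: dict[str, str] = {}
    _evolve_down(species_tree.root, root_seq, params.sub_rate, rng, primary)
    out = {sp: [seq] for sp, seq in primary.items()}
    if rng.random() < params.dup_prob:
        # a second, independently evolved copy lands in one random species
        extra: dict[str, str] = {}
        _evolve_down(species_tree.root, root_seq, params.sub_rate, rng, extra)
        species = sorted(primary)
        target = species[int(rng.integers(len(species)))]
        out[target].append(extra[target])
    return out


def simulate_families(species_tree: Tree, params: SimulationParams) -> list[dict[str, list[str]]]:
    return [evolve_family(species_tree, params, f) for f in range(params.n_families)]


# ---------------------------------------------------------------------------
# emission in the three input modes
# ---------------------------------------------------------------------------

def _spacer(length: int) -> str:
    reps = (length + len(SPACER_MOTIF) - 1) // len(SPACER_MOTIF)
    return (SPACER_MOTIF * reps)[:length]


def _species_genes(
    families: Sequence[dict[str, list[str]]], species: str
) -> list[tuple[str, int, int, str]]:
    """(local_id, family_index, copy_index, residues) for one species."""
    out = []
    for f, fam in enumerate(families):
        for c, seq in enumerate(fam.get(species, [])):
            local = f"f{f:04d}" if c == 0 else f"f{f:04d}c{c}"
            out.append((local, f, c, seq))
    return out


def emit_inputs(
    families: Sequence[dict[str, list[str]]],
    species_tree: Tree,
    params: SimulationParams,
    mode,
    out_dir,
) -> dict:
    """Write per-species input files in the requested mode(s).

    ``mode`` is either one of ``{"cds", "gff3", "genome"}`` for all species
    or a dict species -> mode.  Returns a manifest: species -> dict with
    ``mode`` and file paths.  A ground-truth table (species, local gene id,
    family, copy) and the true species tree are always written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species = sorted(species_tree.leaf_labels())
    modes = {sp: mode for sp in species} if isinstance(mode, str) else dict(mode)
    rng = np.random.default_rng([params.seed, 307])
    # strand assignment is drawn once per (species, gene) independent of
    # mode, so gff3 and genome emissions of the same system are identical
    manifest: dict[str, dict] = {}
    truth_lines = []
    for si, sp in enumerate(species):
        genes = _species_genes(families, sp)
        for local, f, c, _seq in genes:
            truth_lines.append(f"{sp}\t{local}\t{f}\t{c}\n")
        m = modes[sp]
        entry: dict = {"mode": m}
        if m == "cds":
            path = out_dir / f"{sp}.cds.fasta"
            write_fasta(
                (SeqRecord(id=local, residues=seq) for local, _f, _c, seq in genes),
                path,
            )
            entry["cds"] = str(path)
        elif m in ("gff3", "genome"):
            strands = ["+" if rng.random() < 0.5 else "-" for _ in genes]
            spacer = _spacer(params.spacer_length)
            parts = [spacer]
            features = []
            pos = len(spacer)
            for (local, _f, _c, seq), strand in zip(genes, strands):
                planted = seq if strand == "+" else reverse_complement(seq)
                start1 = pos + 1  # GFF3 1-based inclusive
                end1 = pos + len(planted)
                features.append((start1, end1, strand, local))
                parts.append(planted)
                parts.append(spacer)
                pos = end1 + len(spacer)
            contig = "".join(parts)
            gpath = out_dir / f"{sp}.genome.fasta"
            write_fasta([SeqRecord(id=f"{sp}_chr1", residues=contig)], gpath)
            entry["genome"] = str(gpath)
            if m == "gff3":
                apath = out_dir / f"{sp}.gff3"
                with apath.open("w") as fh:
                    fh.write("##gff-version 3\n")
                    for start1, end1, strand, local in features:
                        fh.write(
                            f"{sp}_chr1\tsim\tCDS\t{start1}\t{end1}\t.\t"
                            f"{strand}\t0\tID=cds_{local};Parent={local}\n"
                        )
                entry["gff3"] = str(apath)
        else:
            raise ValueError(f"unknown mode {m!r} for species {sp}")
        manifest[sp] = entry
    (out_dir / "ground_truth.tsv").write_text("".join(truth_lines))
    (out_dir / "true_species_tree.nwk").write_text(write_newick(species_tree) + "\n")
    return manifest


def random_genome(species_id: str, length: int, seed: int) -> SeqRecord:
    """An unrelated random contig: the homology-free planted species used
    to exercise the omission path."""
    rng = np.random.default_rng([seed, 401])
    residues = "".join(_BASES[int(i)] for i in rng.integers(4, size=length))
    return SeqRecord(id=f"{species_id}_chr1", residues=residues, species_id=species_id)


def emit_random_species(species_id: str, length: int, seed: int, out_dir) -> str:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{species_id}.genome.fasta"
    write_fasta([random_genome(species_id, length, seed)], path)
    return str(path)


def read_ground_truth(path) -> dict[tuple[str, str], int]:
    """(species, local_id) -> family index."""
    out: dict[tuple[str, str], int] = {}
    for line in Path(path).read_text().splitlines():
        sp, local, fam, _copy = line.split("\t")
        out[(sp, local)] = int(fam)
    return out
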