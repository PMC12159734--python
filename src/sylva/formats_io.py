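"""Readers and writers for the pipeline's on-disk formats.

Three formats cross the package boundary: FASTA (all sequence input and
output), GFF3 (CDS extraction from annotated genomes) and Newick (every
tree).  Sequences are nucleotide-only; anything outside ``{A,C,G,T,N}`` is
mapped to ``N`` on read (lowercase is uppercased, ``U`` becomes ``T``).

Internally all coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at this boundary and nowhere else.

Gene identifiers are composed as ``"<species_id>|<local_id>"`` so that every
leaf label in a gene tree maps back to its species by splitting on the first
``'|'``; the pipe character is therefore reserved and rejected in user input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

RESERVED_ID_CHAR = "|"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ALPHABET = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Malformed input file (FASTA, GFF3 or Newick)."""


# ---------------------------------------------------------------------------
# sequence records
# ---------------------------------------------------------------------------

@dataclass
class SeqRecord:
    """A raw input sequence (contig, scaffold or provided gene)."""

    id: str
    residues: str
    description: str = ""
    species_id: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


@dataclass
class GeneSeq:
    """A candidate gene sequence with provenance.

    ``origin`` records how the sequence was obtained: provided coding
    sequence (``cds``), extracted from a GFF3 annotation (``annotation``)
    or predicted as an open reading frame (``orf``).
    """

    species_id: str
    gene_id: str
    residues: str
    origin: str  # {"cds", "annotation", "orf"}
    source_contig: Optional[str] = None
    span: Optional[tuple[int, int]] = None  # 0-based half-open, forward strand
    strand: Optional[str] = None  # "+" or "-"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"gene {self.gene_id}: empty sequence")
        if not self.gene_id.startswith(self.species_id + RESERVED_ID_CHAR):
            raise ValueError(
                f"gene_id {self.gene_id!r} does not encode species "
                f"{self.species_id!r} as a prefix"
            )


def make_gene_id(species_id: str, local_id: str) -> str:
    return f"{species_id}{RESERVED_ID_CHAR}{local_id}"


def species_of(gene_id: str) -> str:
    """Recover the species from a composed gene identifier."""
    sp, sep, _ = gene_id.partition(RESERVED_ID_CHAR)
    if not sep:
        raise ValueError(f"gene_id {gene_id!r} carries no species prefix")
    return sp


def normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T, and map anything outside {A,C,G,T,N} to N.

    Returns the cleaned string and the number of substituted characters.
    """
    s = raw.upper().replace("U", "T")
    cleaned = _NON_ALPHABET.sub("N", s)
    n_subst = sum(1 for a, b in zip(s, cleaned) if a != b)
    return cleaned, n_subst


def _reverse_complement(residues: str) -> str:
    # orf_finder re-exports this as the public reverse_complement op
    return residues.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    species_id: str = "",
    allow_reserved: bool = False,
) -> list[SeqRecord]:
    """Read a (multi-line) FASTA file into validated records.

    Duplicate identifiers and records with empty bodies are errors; the
    reserved ``'|'`` character is rejected in identifiers unless
    ``allow_reserved`` is set (used when re-reading the package's own
    intermediate files, whose ids are composed gene ids).
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    n_subst_total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if not allow_reserved and RESERVED_ID_CHAR in rec.id:
            raise FormatError(
                f"{path}: id {rec.id!r} contains reserved character "
                f"{RESERVED_ID_CHAR!r}"
            )
        residues, n_subst = normalize_residues(str(rec.seq))
        n_subst_total += n_subst
        if not residues:
            raise FormatError(f"{path}: empty body for record {rec.id!r}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SeqRecord(id=rec.id, residues=residues, description=desc,
                      species_id=species_id)
        )
    if n_subst_total:
        logger.info("%s: %d non-ACGTN characters mapped to N", path, n_subst_total)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 CDS extraction
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_attributes(col: str) -> dict[str, str]:
    return {k.strip(): v.strip() for k, v in _ATTR_RE.findall(col)}


def extract_cds_from_gff3(
    gff3_path: str | Path,
    genome: list[SeqRecord],
    species_id: str = "",
) -> list[GeneSeq]:
    """Extract spliced coding sequences from a GFF3 annotation.

    CDS features sharing a parent are concatenated in ascending genomic
    order and reverse-complemented as a whole when on the minus strand.
    GFF3 coordinates are 1-based inclusive; the conversion to the internal
    0-based half-open convention happens here.  Every distinct parent
    becomes its own GeneSeq (isoform deduplication is left to clustering).
    """
    gff3_path = Path(gff3_path)
    contigs = {rec.id: rec.residues for rec in genome}
    # parent -> (contig, strand, [(start0, end0)])
    groups: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    order: list[str] = []
    with gff3_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{gff3_path}:{lineno}: expected 9 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            if seqid not in contigs:
                raise FormatError(
                    f"{gff3_path}:{lineno}: CDS references unknown contig {seqid!r}"
                )
            start1, end1 = int(start), int(end)
            if start1 < 1 or end1 > len(contigs[seqid]) or start1 > end1:
                raise FormatError(
                    f"{gff3_path}:{lineno}: coordinates {start1}..{end1} out of "
                    f"range for contig {seqid!r} (length {len(contigs[seqid])})"
                )
            attributes = _parse_attributes(attrs)
            parent = attributes.get("Parent") or attributes.get("ID")
            if not parent:
                raise FormatError(
                    f"{gff3_path}:{lineno}: CDS feature lacks Parent/ID attribute"
                )
            if strand not in ("+", "-"):
                raise FormatError(f"{gff3_path}:{lineno}: bad strand {strand!r}")
            if parent not in groups:
                groups[parent] = (seqid, strand, [])
                order.append(parent)
            gcontig, gstrand, segs = groups[parent]
            if gcontig != seqid or gstrand != strand:
                raise FormatError(
                    f"{gff3_path}: CDS segments of {parent!r} disagree on "
                    "contig or strand"
                )
            segs.append((start1 - 1, end1))  # to 0-based half-open
    genes: list[GeneSeq] = []
    for parent in order:
        contig, strand, segs = groups[parent]
        segs.sort()
        spliced = "".join(contigs[contig][s:e] for s, e in segs)
        if strand == "-":
            spliced = _reverse_complement(spliced)
        genes.append(
            GeneSeq(
                species_id=species_id,
                gene_id=make_gene_id(species_id, parent),
                residues=spliced,
                origin="annotation",
                source_contig=contig,
                span=(segs[0][0], segs[-1][1]),
                strand=strand,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# trees and Newick
# ---------------------------------------------------------------------------

class TreeNode:
    """One node of a phylogenetic tree."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class Tree:
    """A rooted or unrooted labeled tree.

    Unrooted trees are stored in the conventional rooted shape with a
    trifurcating top node; ``rooted`` records the intended interpretation.
    """

    def __init__(self, root: TreeNode, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "Tree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length, node.support)
            for c in node.children:
                new.add(rec(c))
            return new

        return Tree(rec(self.root), rooted=self.rooted)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({write_newick(self)!r})"


def unroot(tree: Tree) -> Tree:
    """Copy of the tree with a binary root suppressed into a trifurcation
    (the conventional unrooted representation); no-op otherwise."""
    tree = tree.copy()
    tree.rooted = False
    root = tree.root
    if len(root.children) != 2:
        return tree
    internal = [c for c in root.children if not c.is_leaf]
    if not internal:
        return tree
    keep = internal[0]
    other = root.children[0] if keep is root.children[1] else root.children[1]
    if other.length is not None or keep.length is not None:
        other.length = (other.length or 0.0) + (keep.length or 0.0)
    new_root = TreeNode()
    for c in keep.children:
        new_root.add(c)
    new_root.add(other)
    return Tree(new_root, rooted=False)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (unquoted labels, optional lengths/support).

    Internal node labels are read as support values when they parse as
    floats.  Errors report the character offset of the problem.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise FormatError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0
    n = len(s)

    def error(msg: str, at: int):
        raise FormatError(f"Newick parse error at offset {at}: {msg}")

    def parse_label_length(node: TreeNode, internal: bool) -> None:
        nonlocal pos
        start = pos
        while pos < n and s[pos] not in "(),:;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            if internal:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
            else:
                node.label = label
        if pos < n and s[pos] == ":":
            pos += 1
            start = pos
            while pos < n and s[pos] not in "(),:;":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                error(f"bad branch length {s[start:pos]!r}", start)

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < n and s[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                node.add(parse_clade())
                if pos >= n:
                    error("unbalanced parentheses", open_at)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}", pos)
            parse_label_length(node, internal=True)
        else:
            parse_label_length(node, internal=False)
            if node.label is None:
                error("empty leaf label", pos)
        return node

    root = parse_clade()
    if pos != n:
        error(f"trailing characters {s[pos:]!r}", pos)
    tree = Tree(root, rooted=len(root.children) == 2)
    labels = tree.leaf_labels()
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def _fmt_num(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: Tree) -> str:
    """Serialize to Newick: unquoted labels, 6-significant-digit lengths,
    internal support written as internal node labels."""

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            out = node.label or ""
        else:
            out = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.support is not None:
                out += _fmt_num(node.support)
            elif node.label:
                out += node.label
        if node.length is not None:
            out += ":" + _fmt_num(node.length)
        return out

    return rec(tree.root) + ";"


def canonical_newick(tree: Tree) -> str:
    """Topology-only Newick with children sorted by smallest leaf label.

    Used for deterministic tie-breaking and topology comparison; drops
    lengths and support.
    """

    def rec(node: TreeNode) -> tuple[str, str]:
        if node.is_leaf:
            return node.label, node.label
        parts = sorted(rec(c) for c in node.children)
        key = parts[0][0]
        return key, "(" + ",".join(p[1] for p in parts) + ")"

    return rec(tree.root)[1] + ";"
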