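# sylva

A self-contained genome-to-species-tree phylogenomics pipeline. Given
per-species nucleotide FASTA files — provided coding sequences, an
annotated genome (FASTA + GFF3), or bare unannotated scaffolds, mixable
within one run — `sylva` identifies candidate gene sequences, groups
homologs by similarity-based clustering, builds a gene tree per sampled
group, and merges the gene trees into a species tree by quartet-score
maximization. The tree-comparison metrics used to evaluate such trees
(Robinson–Foulds and rooted triplet distance) are built in.

It is aimed at desk-scale comparative genomics: a handful to a few dozen
microbial-sized genomes, no external databases, no cluster scheduler, and
fully reproducible runs under a fixed seed.

## Method

1. **Gene identification.** Per species, with priority: provided CDS >
   CDS extracted from a GFF3 annotation > open reading frames
   (ATG→stop, all six frames, ≥ 300 nt by default) from bare scaffolds.
2. **All-vs-all similarity.** A seeded (11-mer) banded Smith–Waterman
   search with BLASTN-like scoring and Karlin–Altschul statistics
   `E = K·m·n·exp(−λS)`; pairs with `E ≤ 1e-20` (configurable) count as
   linked.
3. **Homolog grouping.** Pairwise distances
   `d(i,j) = 1 − best_raw(i,j)/min(self(i), self(j))` feed DBSCAN
   (`eps = 0.7`, `min_pts = 3`); clusters outside [3, 100] members are
   dropped and up to 50 groups are sampled uniformly at random.
4. **Gene trees.** Per group: neighbor-joining–guided progressive
   alignment with affine gaps, then a neighbor-joining tree on
   Jukes–Cantor distances, `d = −(3/4)·ln(1 − (4/3)p)`. Leaves keep gene
   ids, so paralogs (multicopy) are allowed.
5. **Species tree.** The quartet score — the weighted number of gene-tree
   quartet topologies a candidate agrees with, with multicopy genes
   contributing fractionally per leaf combination — is maximized exactly
   (exhaustive enumeration, ≤ 8 species) or by seeded greedy insertion +
   NNI hill climbing. Internal branches carry the dominant quartet
   frequency `q` as support and a coalescent-unit length
   `−ln(1.5(1−q))` (capped at 10); species appearing in no sampled group
   are omitted and reported.

## Worked example

Generate a synthetic 6-species system with a known species tree, run the
pipeline on it, and compare the estimate against the truth:

```sh
sylva make-fixtures --out demo --seed 11 --n-species 6 --n-families 15
sylva run --config demo/run.cfg
sylva compare --ref demo/true_species_tree.nwk --est demo/out/species_tree.nwk
```

The run prints the estimated species tree,

```
(s00:1,s01:1,(s02:1,(s03:1,(s04:1,s05:1)0.966667:2.99573)0.933333:2.30259)0.755556:1.0033);
```

an unrooted tree (trifurcating first node) whose internal labels are
quartet supports — e.g. 96.7% of sampled gene-tree quartets around the
`(s04,s05)` branch agree with it — and whose internal branch lengths are
in coalescent units (terminal branches are fixed at 1). The comparison
prints

```
rf_raw  rf_normalized  one_sided_rf  triplet_error  n_shared_leaves
0       0.0000         0.0000        0.5000         6
```

a normalized Robinson–Foulds distance of 0% (every bipartition of the
true tree is recovered; 0% is an identical tree, 100% would share no
bifurcations). The triplet error compares *rooted* topologies: the
pipeline's output is unrooted and is midpoint-rooted for this metric, so
the triplet error mostly reflects root placement once RF is 0.

All outputs land in the configured `output_dir`: `species_tree.nwk`,
`gene_trees/*.nwk`, `alignments/*.fasta`, `groups.tsv`,
`omitted_species.txt`, `run.log`, and a `.cache/` directory that lets a
rerun skip unchanged stages.

## Scope and design notes

`sylva` deliberately embeds small, deterministic stand-ins for the heavy
external tools a production pipeline would call (BLAST, MAFFT, RAxML-NG,
ASTRAL): the search, aligner, and tree builders are in-package, and each
stage boundary accepts an external backend through the same file formats
(outfmt-6 TSV, FASTA in/aligned FASTA out, alignment in/Newick out).
See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
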