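# Methods

This note documents the models, algorithms, parameter defaults, and
numerical conventions implemented in `sylva`, and what the synthetic
test system does and does not establish about behavior on real data.

## Pipeline model

The pipeline estimates a species tree from per-species nucleotide
sequence sets under the standard gene-tree/species-tree paradigm:
homologous sequences are grouped across species, each group yields an
independent estimate of a gene tree, and the species tree is the
topology most compatible with the gene trees under the multispecies
coalescent's quartet prediction (for any four species, the true species
topology is the most frequent unrooted gene-tree quartet). No claim is
made that groups are orthologous single-copy genes: grouping is purely
similarity-density based, and paralogy is absorbed downstream by
multicopy-aware quartet weighting rather than filtered out.

## Gene identification

Priority per species: provided CDS, else CDS spliced from a GFF3
annotation (segments per parent concatenated in ascending genomic order,
reverse-complemented as a whole on the minus strand), else ORFs.

ORF definition: in each of six frames, the region from the most 5'
in-frame ATG after the previous in-frame stop through the next stop,
inclusive. One ORF per (frame, stop), so nested starts do not multiply
candidates. ORFs truncated by contig ends are discarded. Codons
containing `N` never match ATG or a stop.

* `min_orf_len = 300` nt (~100 aa). The all-vs-all search cost scales
  with the square of the candidate count, and short spurious ORFs
  dominate raw six-frame scans; 300 nt is the conventional cutoff that
  suppresses them while keeping typical microbial genes.

## Similarity search and statistics

An exact k-mer index (word size 11, words containing `N` skipped)
proposes candidate subjects; each candidate is scored by Smith–Waterman
with affine gaps (open `5 + 2`, extend `2`, match `+2`, mismatch `−3`)
restricted to a band of half-width 32 around the seed-richest diagonal
(ties broken toward the smallest diagonal). Significance uses
Karlin–Altschul statistics with `λ = 0.625`, `K = 0.41` (BLASTN-like
constants for these rewards/penalties), `m` the query length and `n` the
total database length; effective-length corrections are omitted because
only the threshold ordering of pairs is consumed downstream. The default
threshold `E ≤ 1e-20` can be raised for distantly related inputs or
lowered for very close ones.

The module is a pure function of its inputs: no randomness, and the
banded heuristic is deterministic. The band can in principle truncate a
gappy optimal alignment; for the threshold semantics used here that only
risks losing marginal pairs, and the full-matrix algorithm is available
(`smith_waterman`) and is the tested reference.

## Distance and clustering

The mapping from search results to clustering distances is

    s(i,j) = best_raw(i,j) / min(self(i), self(j)),  clamped to [0,1]
    d(i,j) = 1 − s(i,j);   d = 1 when no direction passes the E cutoff

i.e. the better direction of an asymmetric pair normalized by the weaker
self-alignment. It is bounded, symmetric, zero for identical sequences,
and uses only quantities the search already produces.

DBSCAN is implemented to be order-deterministic: ids are scanned
lexicographically; core points (≥ `min_pts` neighbors within `eps`,
self included) form clusters as connected components under the
eps-neighbor relation; border points join their first core neighbor in
scan order; cluster indices follow the first core point encountered.
Classic DBSCAN leaves the border-tie rule unspecified — fixing it makes
runs byte-reproducible.

* `dbscan_eps = 0.7`: under the score-ratio distance, ~0.3 score ratio
  is roughly 35–40% nucleotide divergence, a generous within-family
  radius; families that are separated at all under the E-value cutoff
  sit at `d = 1`.
* `dbscan_min_pts = min_group_size = 3`, `max_group_size = 100`: a
  cluster smaller than the minimum could never survive the size filter.
* Up to `max_gene_trees = 50` groups are sampled uniformly without
  replacement with the run seed.

Single-species groups are retained if they pass the size filter; they
simply contribute no quartets.

## Alignment and gene trees

Progressive alignment: a neighbor-joining guide tree on k-mer profile
distances (`k = 6`; distance `1 − shared/min` over k-mer multisets),
then bottom-up profile–profile global alignment with affine gaps.
Columns are frequency vectors over `{A,C,G,T,N,-}`; the column-pair
score is the expected pair score with `N` scoring 0 against everything
and an existing gap scoring `−gap_extend` against a base (linear charge
for present gaps, affine only for new ones). DP ties break diagonal >
up > left. For two sequences this is exactly global pairwise
Needleman–Wunsch–Gotoh, which is how it is validated. No iterative
refinement.

Gene trees: neighbor joining (Q criterion, Saitou–Nei branch lengths,
negatives clamped to 0 after estimation, Q ties broken by the
lexicographically smallest pair of cluster representatives) on
Jukes–Cantor distances computed over columns where both rows carry a
plain base. Saturated pairs (`p ≥ 3/4`, or no comparable column) get
`d_max = 5.0` substitutions/site to keep NJ finite. Groups with fewer
than three members are skipped with a warning.

Both the aligner and the tree builder are deliberately simple,
deterministic stand-ins for heavyweight tools; external backends plug in
through the stage file formats (FASTA/aligned FASTA/Newick) without
touching the rest of the pipeline.

## Species-tree estimation

The objective is the quartet score: for every 4-species subset, each
gene tree distributes total weight 1 over the three unrooted topologies,
each one-leaf-per-species combination contributing equally (so a gene
with two copies of one species splits its vote). When a gene tree has
more than 100 combinations for a subset, 100 are sampled with the run
seed. This uniform per-copy weighting is a deliberate, simpler
alternative to duplication-tagged multicopy scoring: it is well defined,
exactly recomputable by brute force, and agrees with it in tests.

Optimization: exhaustive enumeration of unrooted topologies by stepwise
leaf insertion for ≤ `exact_limit = 8` species (10 395 topologies at
n = 8), otherwise greedy insertion in a seeded random order followed by
nearest-neighbor-interchange hill climbing, best of 3 restarts. All ties
break toward the lexicographically smallest canonical Newick string.

Branch annotation: for an internal branch with surrounding subtree
groups A,B | C,D, support is the fraction `q` of tallied quartet weight
(one species per group) agreeing with AB|CD, and the length is the
multispecies-coalescent transform `−ln(1.5(1−q))`, 0 at the no-signal
point `q = 1/3` and capped at 10 (infinite at `q = 1`). Terminal
branches have no discordance signal and are fixed at 1.0. These are
coalescent units, not substitutions/site — midpoint rooting on them is
essentially arbitrary, which matters for the triplet metric (below).

Species present in the input but absent from every sampled group cannot
be placed; they are omitted from the tree, listed in
`omitted_species.txt`, and warned about. Runs need at least four placed
species, and a run with zero surviving groups fails with the advice to
raise the E-value threshold.

## Tree metrics

Robinson–Foulds: splits counted over the shared leaf set after
restriction (logged), reported raw and normalized to
`100·|S₁ Δ S₂|/(|S₁|+|S₂|)` percent. For non-binary references a
one-sided variant `100·|S₁∖S₂|/|S₁|` is also reported: extra resolution
in the estimate is not an error when the reference does not claim full
resolution.

Triplet distance: fraction of 3-leaf subsets where both rooted trees are
resolved and disagree; reference-unresolved triplets count as agreement
by default (switchable via `penalize_extra_resolution`). The metric
requires rooted trees; `compare_trees` midpoint-roots the unrooted
estimate (or roots at a given outgroup). Because the estimate's branch
lengths are coalescent units with unit terminals, midpoint rooting is
weakly determined, and triplet error can be large even at RF 0 — an
expected artifact worth keeping in mind when reading triplet numbers.
Branch lengths never enter either metric.

## Synthetic data

The generator emulates the pipeline's whole input space from known
ground truth: a Yule species tree (uniform lineage splits, exponential
waiting times) normalized to height 1; per family a random
stop-free ORF of `gene_length = 600` nt evolved down the tree; emission
as per-species CDS FASTA, genome + GFF3, or genome only, plus a
ground-truth table and the true tree.

* Substitution model: each branch applies one Bernoulli substitution
  event per site with probability `branch_length × sub_rate`
  (`sub_rate = 0.1` over unit height), uniform over the other three
  bases. This is a discrete single-event approximation of Jukes–Cantor;
  its exact pairwise closed form
  `p = 3/4·(1 − Π_edges(1 − 4/3·l·r))` is what the tests check against.
  Start/stop codons are held fixed and internal in-frame stops re-rolled
  so every copy stays a clean ORF.
* `dup_prob = 0.1`: one independently evolved extra copy in one random
  species per affected family, exercising the multicopy path.
* Genomes interleave genes (random strand) with `spacer_length = 200` nt
  spacers of the motif `TTAA` repeated — a stop codon in every frame on
  both strands, no ATG, and self-reverse-complementary — so planted ORFs
  are recovered exactly and no ORF bridges genes.

What the synthetic system does **not** emulate: indels (alignments of
simulated families are essentially gap-free), rate heterogeneity across
sites or lineages, gene loss, horizontal transfer, repeats, and
assembly artifacts. Passing the recovery tests therefore demonstrates
the pipeline's machinery is correct and consistent across input modes,
not that its accuracy transfers to hard real datasets; the aligner and
NJ stand-ins in particular would be the first components to swap for
external tools on divergent real genomes.

## Orchestration, determinism, problem sizes

Stages communicate through pure functions and are cached on disk keyed
by a hash of the configuration and input file contents, so a rerun
recomputes only stages downstream of a change. The parallel map
preserves input order and gives results independent of worker count;
the similarity stage batches 50 queries per task. All randomness (group
sampling, quartet subsampling, heuristic restarts) derives from the
single configured seed (default 42), making runs bit-identical for a
fixed configuration; vary the seed to explore sampling variability.

The test suite and the acceptance script run the full pipeline at
8 species × 40 families × 600 nt — small enough for exhaustive
species-tree search and brute-force oracles while exercising every stage
including multicopy handling — and the end-to-end recovery check demands
normalized RF 0% to the generating tree in ≥ 18 of 20 seeded replicates.

## Known limitations

* Quartet tallies are stored per covered 4-subset: fine to ~25 species,
  not designed for hundreds.
* The banded search can miss highly gapped homologies; raise the band
  half-width or plug in an external search for such data.
* The heuristic species-tree search is a local optimizer; with few,
  discordant gene trees it can return a local optimum (it matches the
  exact optimum in ≥ 18/20 random n = 8 instances in tests).
* Terminal branch lengths are uninformative placeholders (1.0), and the
  output tree is unrooted.
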