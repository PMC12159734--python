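"""Simulator: Yule trees, Jukes-Cantor evolution, input-mode emission."""

import math

import numpy as np
import pytest

from sylva.formats_io import read_fasta, write_newick, extract_cds_from_gff3
from sylva.orf_finder import STOP_CODONS, find_orfs
from sylva.synthetic_data import (
    SPACER_MOTIF,
    SimulationParams,
    emit_inputs,
    evolve_family,
    random_genome,
    read_ground_truth,
    simulate_families,
    simulate_species_tree,
)

from oracles import path_length_matrix


class TestSpeciesTree:
    def test_structure_and_height(self):
        t = simulate_species_tree(4, seed=0)
        assert len(t.leaves()) == 4
        internals = [n for n in t.root.walk() if not n.is_leaf]
        assert len(internals) == 3
        _, D = path_length_matrix(t)
        # ultrametric of height 1: all leaf pairs at distance <= 2, root at 1
        depths = _leaf_depths(t)
        assert all(abs(d - 1.0) < 1e-9 for d in depths.values())

    def test_determinism(self):
        a = simulate_species_tree(7, seed=5)
        b = simulate_species_tree(7, seed=5)
        assert write_newick(a) == write_newick(b)
        c = simulate_species_tree(7, seed=6)
        assert write_newick(a) != write_newick(c)

    def test_binary_and_ultrametric_across_seeds(self):
        for seed in range(40):
            n = 4 + seed % 5
            t = simulate_species_tree(n, seed)
            for node in t.root.walk():
                if not node.is_leaf:
                    assert len(node.children) == 2
            depths = _leaf_depths(t)
            assert max(abs(d - 1.0) for d in depths.values()) < 1e-9


def _leaf_depths(tree):
    out = {}

    def rec(node, acc):
        acc = acc + (node.length or 0.0)
        if node.is_leaf:
            out[node.label] = acc
        for c in node.children:
            rec(c, acc)

    rec(tree.root, 0.0)
    return out


class TestEvolveFamily:
    def test_zero_rate_identical_sequences(self):
        t = simulate_species_tree(5, seed=1)
        params = SimulationParams(n_species=5, n_families=1, sub_rate=0.0,
                                  dup_prob=0.0, seed=1)
        fam = evolve_family(t, params, 0)
        seqs = {s for copies in fam.values() for s in copies}
        assert len(seqs) == 1

    def test_sequences_remain_clean_orfs(self):
        t = simulate_species_tree(6, seed=2)
        params = SimulationParams(n_species=6, n_families=1, sub_rate=0.5, seed=2)
        fam = evolve_family(t, params, 0)
        for copies in fam.values():
            for seq in copies:
                assert seq.startswith("ATG") and seq[-3:] in STOP_CODONS
                internal = [seq[i : i + 3] for i in range(3, len(seq) - 3, 3)]
                assert not set(internal) & STOP_CODONS

    def test_dup_prob_one_gives_exactly_one_twocopy_species(self):
        t = simulate_species_tree(6, seed=3)
        params = SimulationParams(n_species=6, n_families=1, dup_prob=1.0, seed=3)
        fam = evolve_family(t, params, 0)
        copy_counts = sorted(len(c) for c in fam.values())
        assert copy_counts == [1, 1, 1, 1, 1, 2]

    def test_divergence_tracks_jc_expectation(self):
        """Mean observed p-distance between two fixed leaves is within 3
        standard errors of the closed form for the per-branch substitution
        model: a branch of length l applies a substitution event with
        probability l*sub_rate, so the site-difference probability is
        p = 3/4 * (1 - prod_edges (1 - 4/3 * l_e * sub_rate))."""
        n_fam = 200
        t = simulate_species_tree(5, seed=4)
        params = SimulationParams(n_species=5, n_families=n_fam, sub_rate=0.2,
                                  dup_prob=0.0, seed=4)
        ids = sorted(t.leaf_labels())
        a, b = ids[0], ids[1]
        lam = 1.0
        for l in _path_edge_lengths(t, a, b):
            lam *= 1.0 - (4.0 / 3.0) * l * params.sub_rate
        expected_p = 0.75 * (1 - lam)
        ps = []
        for f in range(n_fam):
            fam = evolve_family(t, params, f)
            x, y = fam[a][0], fam[b][0]
            # only interior sites mutate; compare those
            xi, yi = x[3:-3], y[3:-3]
            ps.append(sum(c1 != c2 for c1, c2 in zip(xi, yi)) / len(xi))
        mean_p = np.mean(ps)
        se = np.std(ps) / math.sqrt(n_fam)
        # small excess over the closed form is expected from stop-codon
        # re-rolls; allow it in the tolerance floor
        assert abs(mean_p - expected_p) < max(3 * se, 0.015)


def _path_edge_lengths(tree, a, b):
    nodes = {n.label: n for n in tree.leaves()}
    anc_a = []
    node = nodes[a]
    while node is not None:
        anc_a.append(node)
        node = node.parent
    anc_ids = {id(n): i for i, n in enumerate(anc_a)}
    node = nodes[b]
    lengths = []
    while id(node) not in anc_ids:
        lengths.append(node.length or 0.0)
        node = node.parent
    for up in anc_a[: anc_ids[id(node)]]:
        lengths.append(up.length or 0.0)
    return lengths


class TestEmission:
    @pytest.fixture
    def system(self):
        params = SimulationParams(n_species=5, n_families=6, dup_prob=0.5, seed=9)
        tree = simulate_species_tree(5, seed=9)
        return tree, simulate_families(tree, params), params

    def test_cds_mode_record_counts(self, system, tmp_path):
        tree, fams, params = system
        manifest = emit_inputs(fams, tree, params, "cds", tmp_path)
        truth = read_ground_truth(tmp_path / "ground_truth.tsv")
        for sp, entry in manifest.items():
            records = read_fasta(entry["cds"])
            expected = sum(len(f.get(sp, [])) for f in fams)
            assert len(records) == expected
            for rec in records:
                assert (sp, rec.id) in truth

    def test_gff3_mode_round_trips_through_extraction(self, system, tmp_path):
        tree, fams, params = system
        cds_dir = tmp_path / "cds"
        gff_dir = tmp_path / "gff"
        emit_inputs(fams, tree, params, "cds", cds_dir)
        manifest = emit_inputs(fams, tree, params, "gff3", gff_dir)
        for sp, entry in manifest.items():
            genome = read_fasta(entry["genome"])
            extracted = {
                g.gene_id.split("|", 1)[1]: g.residues
                for g in extract_cds_from_gff3(entry["gff3"], genome, sp)
            }
            provided = {
                r.id: r.residues for r in read_fasta(cds_dir / f"{sp}.cds.fasta")
            }
            assert extracted == provided

    def test_genome_mode_orf_recovery(self, system, tmp_path):
        """Nearly every planted gene is recovered as an exact-span ORF."""
        tree, fams, params = system
        manifest = emit_inputs(fams, tree, params, "genome", tmp_path)
        planted_total = 0
        recovered = 0
        for sp, entry in manifest.items():
            genome = read_fasta(entry["genome"])
            orf_seqs = {
                o.residues
                for rec in genome
                for o in find_orfs(rec, min_orf_len=params.gene_length)
            }
            for f in fams:
                for seq in f.get(sp, []):
                    planted_total += 1
                    recovered += seq in orf_seqs
        assert recovered >= 0.95 * planted_total

    def test_spacer_motif_properties(self):
        both = SPACER_MOTIF * 20
        from sylva.orf_finder import reverse_complement
        assert "ATG" not in both and "ATG" not in reverse_complement(both)
        # a stop codon in every frame
        for frame in range(3):
            codons = {both[i : i + 3] for i in range(frame, len(both) - 2, 3)}
            assert codons & STOP_CODONS

    def test_mixed_modes_per_species(self, system, tmp_path):
        tree, fams, params = system
        species = sorted(tree.leaf_labels())
        modes = {sp: ("cds", "gff3", "genome")[i % 3] for i, sp in enumerate(species)}
        manifest = emit_inputs(fams, tree, params, modes, tmp_path)
        for sp in species:
            assert manifest[sp]["mode"] == modes[sp]

    def test_random_genome_determinism(self):
        a = random_genome("x", 500, 7)
        b = random_genome("x", 500, 7)
        assert a.residues == b.residues
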