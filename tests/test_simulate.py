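"""Tests for the synthetic benchmark generator."""

import math

import numpy as np
import pytest

from conftest import enumerate_unrooted_topologies, edges_to_newick
from phylomarkers.phylo_io import parse_newick, read_hit_table
from phylomarkers.simulate import (
    SimulationConfig,
    evolve_sequences,
    expected_mismatch_fraction,
    floor_internal_branches,
    nni_perturb,
    synthesize_benchmark,
    synthesize_hit_tables,
    yule_tree,
)
from phylomarkers.tree_build import distance_matrix_from_tree
from phylomarkers.tree_compare import bipartition_set, rf_distance


class TestYuleTree:
    def test_three_leaves(self):
        tree = yule_tree(3, seed=0)
        assert tree.n_leaves == 3
        assert bipartition_set(tree) == frozenset()

    def test_determinism(self):
        from phylomarkers.phylo_io import write_newick

        assert write_newick(yule_tree(12, seed=9)) == write_newick(
            yule_tree(12, seed=9)
        )

    def test_split_count(self):
        assert len(bipartition_set(yule_tree(20, seed=1))) == 17

    def test_binary_with_positive_lengths(self):
        tree = yule_tree(15, seed=4)
        assert tree.is_binary()
        assert all(l > 0 for _, _, l in tree.edges())

    def test_too_small(self):
        with pytest.raises(ValueError):
            yule_tree(2)

    def test_height_scaling(self):
        tree = yule_tree(10, seed=3, height=0.5)
        dm = distance_matrix_from_tree(tree)
        assert dm.d.max() / 2 == pytest.approx(0.5)

    def test_floor_internal_branches(self):
        tree = floor_internal_branches(yule_tree(10, seed=3), 0.07)
        labels = tree.leaf_nodes()
        internal = [
            l
            for u, v, l in tree.edges()
            if u not in labels and v not in labels
        ]
        assert min(internal) >= 0.07


class TestNNIPerturb:
    def test_zero_moves_identity(self):
        tree = yule_tree(10, seed=5)
        assert bipartition_set(nni_perturb(tree, 0)) == bipartition_set(tree)

    def test_leaves_preserved(self):
        tree = yule_tree(10, seed=5)
        assert nni_perturb(tree, 7, seed=1).leaves == tree.leaves

    def test_single_move_is_rf_two(self):
        for seed in range(10):
            tree = yule_tree(8, seed=seed)
            assert rf_distance(nni_perturb(tree, 1, seed=seed), tree)[0] == 2

    def test_single_move_lands_on_enumerated_neighbour(self):
        # oracle: on 5 leaves the NNI neighbours of a tree are exactly the
        # topologies at RF 2; enumerate all 15 and verify membership
        base = yule_tree(5, seed=11)
        topologies = enumerate_unrooted_topologies(sorted(base.leaves))
        trees = [parse_newick(edges_to_newick(e)) for e in topologies]
        base_match = [t for t in trees if rf_distance(t, base)[0] == 0]
        assert len(base_match) == 1
        neighbours = {
            i
            for i, t in enumerate(trees)
            if rf_distance(t, base)[0] == 2
        }
        for seed in range(12):
            moved = nni_perturb(base, 1, seed=seed)
            (idx,) = [
                i
                for i, t in enumerate(trees)
                if rf_distance(t, moved)[0] == 0
            ]
            assert idx in neighbours

    def test_non_binary_rejected(self):
        star = parse_newick("(A,B,C,D,E);")
        with pytest.raises(ValueError, match="binary"):
            nni_perturb(star, 1)


class TestEvolveSequences:
    def test_zero_rate_identical(self):
        tree = yule_tree(6, seed=2)
        aln = evolve_sequences(tree, 50, rate_multiplier=0.0, seed=3)
        seqs = {seq for _, seq in aln.rows}
        assert len(seqs) == 1

    def test_determinism(self):
        tree = yule_tree(6, seed=2)
        a1 = evolve_sequences(tree, 100, seed=7)
        a2 = evolve_sequences(tree, 100, seed=7)
        assert a1.rows == a2.rows

    def test_mismatch_matches_closed_form(self):
        # two leaves at a known path length; compare the observed mismatch
        # fraction against the analytic value within 3 standard errors
        tree = parse_newick("(X:0.15,Y:0.15,(Z:0.1,W:0.1):0.1);")
        length = 100_000
        aln = evolve_sequences(tree, length, seed=13)
        t = 0.30  # X-Y path length
        expected = expected_mismatch_fraction(t)
        observed = sum(
            a != b for a, b in zip(aln.get("X"), aln.get("Y"))
        ) / length
        se = math.sqrt(expected * (1 - expected) / length)
        assert abs(observed - expected) < 3 * se

    def test_closed_form_values(self):
        assert expected_mismatch_fraction(0.0) == 0.0
        assert expected_mismatch_fraction(1e9) == pytest.approx(0.95)

    def test_nj_recovers_generating_tree(self):
        from phylomarkers.tree_build import NeighborJoiningBuilder

        recovered = 0
        for seed in range(10):
            tree = floor_internal_branches(
                yule_tree(10, seed=seed, height=0.5), 0.03
            )
            aln = evolve_sequences(tree, 5000, seed=seed + 100)
            nj = NeighborJoiningBuilder()(aln)
            recovered += rf_distance(nj, tree)[0] == 0
        assert recovered >= 9

    def test_missing_branch_lengths_rejected(self):
        tree = parse_newick("(A,B,(C,D));")
        with pytest.raises(ValueError, match="branch lengths"):
            evolve_sequences(tree, 10)


class TestSynthesizeBenchmark:
    def test_bookkeeping(self):
        cfg = SimulationConfig(
            n_species=24, n_genes=40, n_concordant=10, rng_seed=0
        )
        ds = synthesize_benchmark(cfg)
        assert len(ds.alignments) == 40
        assert sum(t.concordant for t in ds.truth.values()) == 10
        assert ds.t_set | ds.v_set == ds.species
        assert not ds.t_set & ds.v_set
        assert set(ds.truth) == set(ds.alignments)

    def test_two_thirds_split(self):
        cfg = SimulationConfig(n_species=24, rng_seed=1)
        ds = synthesize_benchmark(cfg)
        assert len(ds.t_set) == 16
        assert len(ds.v_set) == 8

    def test_stratification(self):
        # both sets must intersect each depth-1 clade of the species tree
        # root; recover the root split as the deepest bipartition boundary
        cfg = SimulationConfig(n_species=20, rng_seed=3)
        ds = synthesize_benchmark(cfg)
        assert len(ds.t_set) == round(2 / 3 * 20)

    def test_concordant_genes_on_species_tree(self):
        cfg = SimulationConfig(
            n_species=10, n_genes=6, n_concordant=6, rng_seed=2
        )
        ds = synthesize_benchmark(cfg)
        for t in ds.truth.values():
            assert t.concordant
            assert rf_distance(t.tree, ds.species_tree)[0] == 0

    def test_discordant_gene_trees_differ(self):
        cfg = SimulationConfig(
            n_species=12,
            n_genes=8,
            n_concordant=0,
            discordance_nni_range=(2, 4),
            rng_seed=4,
        )
        ds = synthesize_benchmark(cfg)
        for t in ds.truth.values():
            assert 2 <= t.nni_moves <= 4

    def test_determinism(self):
        cfg = SimulationConfig(n_species=10, n_genes=5, n_concordant=2, rng_seed=6)
        d1 = synthesize_benchmark(cfg)
        d2 = synthesize_benchmark(cfg)
        assert d1.t_set == d2.t_set
        for g in d1.alignments:
            assert d1.alignments[g].rows == d2.alignments[g].rows

    def test_separability(self):
        # mean RF of concordant gene trees to the species tree is below the
        # mean over genes perturbed by >= 2 moves, for built trees
        from phylomarkers.tree_build import NeighborJoiningBuilder

        for seed in range(3):
            cfg = SimulationConfig(
                n_species=12,
                n_genes=12,
                n_concordant=5,
                gene_length_range=(2000, 2000),
                discordance_nni_range=(2, 5),
                rng_seed=seed,
            )
            ds = synthesize_benchmark(cfg)
            builder = NeighborJoiningBuilder()
            rf_conc, rf_disc = [], []
            for gid, aln in ds.alignments.items():
                rf = rf_distance(builder(aln), ds.species_tree)[0]
                (rf_conc if ds.truth[gid].concordant else rf_disc).append(rf)
            assert np.mean(rf_conc) < np.mean(rf_disc)

    def test_write_round_trip(self, benchmark_small, tmp_path):
        from phylomarkers.phylo_io import read_fasta_alignment, read_newick

        benchmark_small.write(tmp_path)
        tree = read_newick(tmp_path / "species_tree.nwk")
        assert (
            rf_distance(tree, benchmark_small.species_tree)[0] == 0
        )
        gene = sorted(benchmark_small.alignments)[0]
        aln = read_fasta_alignment(tmp_path / "genes" / f"{gene}.fasta")
        assert aln.rows == benchmark_small.alignments[gene].rows


class TestSynthesizeHitTables:
    def test_no_noise_all_recovered(self):
        from phylomarkers.orthology import single_copy_from_seed

        cfg = SimulationConfig(n_species=8, n_genes=6, n_concordant=3, rng_seed=1)
        ds = synthesize_benchmark(cfg)
        table = synthesize_hit_tables(ds, 0.0, 0.0, seed=0)
        groups = single_copy_from_seed(
            table.seed_species, table.records, ds.species - {table.seed_species}
        )
        assert {g.gene_id.split("|")[1] for g in groups} == set(ds.alignments)

    def test_truth_updated(self):
        cfg = SimulationConfig(n_species=8, n_genes=10, rng_seed=1)
        ds = synthesize_benchmark(cfg)
        synthesize_hit_tables(ds, paralog_rate=0.3, loss_rate=0.3, seed=2)
        planted = [
            t
            for t in ds.truth.values()
            if t.paralog_genomes or t.lost_genomes
        ]
        assert planted  # at these rates something must be planted

    def test_file_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_species=6, n_genes=4, n_concordant=2, rng_seed=3)
        ds = synthesize_benchmark(cfg)
        table = synthesize_hit_tables(ds, 0.2, 0.1, seed=4)
        hits_path = tmp_path / "hits.tsv"
        qlens_path = tmp_path / "qlens.tsv"
        table.write(hits_path, qlens_path)
        records = read_hit_table(hits_path, qlens_path)
        assert len(records) == len(table.records)
        for got, expected in zip(records, table.records):
            assert got.query_id == expected.query_id
            assert got.target_id == expected.target_id
            assert got.target_genome == expected.target_genome
            assert got.e_value == expected.e_value
            assert got.query_coverage == pytest.approx(expected.query_coverage)

    def test_bad_rates_rejected(self, benchmark_small):
        with pytest.raises(ValueError):
            synthesize_hit_tables(benchmark_small, paralog_rate=1.5)
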