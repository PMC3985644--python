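"""Tests for marker ranking, progressive concatenation and subset search."""

import pytest

from conftest import MappingBuilder, trivial_alignment
from phylomarkers.marker_selection import (
    MarkerScore,
    SelectionConfig,
    SelectionError,
    build_reference,
    exhaustive_subset_search,
    progressive_concatenation,
    random_subset_search,
    rank_markers,
    select_minimal_set,
)
from phylomarkers.tree_compare import rf_distance

SPECIES = list("ABCDEF")


@pytest.fixture
def fake_world(six_leaf_trees):
    """Four genes with canned single-gene trees at RF 0, 0, 2, 4."""
    reference, rf2, rf4 = six_leaf_trees
    alignments = {g: trivial_alignment(g, SPECIES) for g in "wxyz"}
    builder = MappingBuilder(
        {
            frozenset("w"): reference,
            frozenset("x"): reference,
            frozenset("y"): rf2,
            frozenset("z"): rf4,
        },
        default=reference,
    )
    return reference, alignments, builder


class TestRankMarkers:
    def test_orders_by_distance(self, fake_world):
        reference, alignments, builder = fake_world
        scores = rank_markers(alignments, reference, builder)
        assert [s.gene_id for s in scores] == ["w", "x", "y", "z"]
        assert [s.distance for s in scores] == [0.0, 0.0, 2.0, 4.0]
        assert [s.rank for s in scores] == [1, 2, 3, 4]

    def test_tie_broken_by_gene_id(self, fake_world):
        reference, alignments, builder = fake_world
        scores = rank_markers(alignments, reference, builder)
        assert scores[0].gene_id == "w"  # both w and x are at 0

    def test_gene_missing_species_excluded(self, six_leaf_trees):
        reference, _, _ = six_leaf_trees
        alignments = {
            "full": trivial_alignment("full", SPECIES),
            "partial": trivial_alignment("partial", SPECIES[:4]),
        }
        builder = MappingBuilder({}, default=reference)
        with pytest.warns(UserWarning, match="partial"):
            scores = rank_markers(alignments, reference, builder)
        assert [s.gene_id for s in scores] == ["full"]

    def test_no_scorable_genes(self, six_leaf_trees):
        reference, _, _ = six_leaf_trees
        alignments = {"p": trivial_alignment("p", SPECIES[:3])}
        with pytest.warns(UserWarning):
            with pytest.raises(SelectionError):
                rank_markers(alignments, reference, MappingBuilder({}))

    def test_simulated_concordant_outrank_perturbed(self):
        from phylomarkers.simulate import SimulationConfig, synthesize_benchmark

        cfg = SimulationConfig(
            n_species=12,
            n_genes=14,
            n_concordant=6,
            gene_length_range=(2000, 2000),
            discordance_nni_range=(3, 5),
            rng_seed=8,
        )
        ds = synthesize_benchmark(cfg)
        scores = rank_markers(ds.alignments, ds.species_tree)
        ranks = {s.gene_id: s.rank for s in scores}
        conc = [g for g, t in ds.truth.items() if t.concordant]
        hard = [g for g, t in ds.truth.items() if t.nni_moves >= 3]
        assert max(ranks[g] for g in conc) < min(ranks[g] for g in hard)


class TestBuildReference:
    def test_single_gene_reference(self, six_leaf_trees):
        reference, _, _ = six_leaf_trees
        alignments = {"only": trivial_alignment("only", SPECIES)}
        builder = MappingBuilder({frozenset(["only"]): reference})
        assert rf_distance(build_reference(alignments, builder), reference)[0] == 0

    def test_concordant_dataset_recovers_species_tree(self, benchmark_small):
        ref = build_reference(benchmark_small.alignments)
        assert rf_distance(ref, benchmark_small.species_tree)[0] == 0

    def test_empty_rejected(self):
        with pytest.raises(SelectionError):
            build_reference({})


def scores_for(gene_ids):
    return [
        MarkerScore(gene_id=g, distance=float(i), rank=i + 1)
        for i, g in enumerate(gene_ids)
    ]


class TestProgressiveConcatenation:
    def test_top_two_sufficient(self, fake_world):
        reference, alignments, builder = fake_world
        cfg = SelectionConfig()
        result = progressive_concatenation(
            scores_for("wxyz"), alignments, reference, cfg, builder
        )
        assert result.genes == ("w", "x")
        assert result.converged

    def test_stopping_rule(self, six_leaf_trees):
        reference, rf2, rf4 = six_leaf_trees
        alignments = {g: trivial_alignment(g, SPECIES) for g in "abcd"}
        builder = MappingBuilder(
            {
                frozenset("ab"): rf4,   # n=2 -> distance 4
                frozenset("abc"): rf2,  # n=3 -> distance 2
                frozenset("abcd"): reference,  # n=4 -> distance 0
            }
        )
        result = progressive_concatenation(
            scores_for("abcd"), alignments, reference, SelectionConfig(), builder
        )
        assert result.genes == ("a", "b", "c", "d")
        assert result.steps == ((2, 4.0), (3, 2.0), (4, 0.0))

    def test_unreachable_cutoff_flags_not_converged(self, six_leaf_trees):
        reference, _, rf4 = six_leaf_trees
        alignments = {g: trivial_alignment(g, SPECIES) for g in "ab"}
        builder = MappingBuilder({}, default=rf4)
        result = progressive_concatenation(
            scores_for("ab"), alignments, reference, SelectionConfig(), builder
        )
        assert result.genes == ("a", "b")
        assert not result.converged

    def test_empty_ranking_rejected(self, fake_world):
        reference, alignments, _ = fake_world
        with pytest.raises(SelectionError):
            progressive_concatenation(
                [], alignments, reference, SelectionConfig()
            )


class TestRandomSubsetSearch:
    def test_finds_smaller_subset_by_exhaustion(self, fake_world):
        # every pair recovers the reference, so a size-2 subset must be
        # found once the (small) candidate space is covered
        reference, alignments, builder = fake_world
        cfg = SelectionConfig(rng_seed=1)
        result = random_subset_search(
            list("wxyz"), list("wxy"), alignments, reference, cfg, builder
        )
        assert len(result.final_set) == 2
        assert result.qualifying

    def test_determinism(self, fake_world):
        reference, alignments, builder = fake_world
        cfg = SelectionConfig(rng_seed=42)
        r1 = random_subset_search(
            list("wxyz"), list("wxyz"), alignments, reference, cfg, builder
        )
        r2 = random_subset_search(
            list("wxyz"), list("wxyz"), alignments, reference, cfg, builder
        )
        assert r1.trace == r2.trace
        assert r1.final_set == r2.final_set

    def test_no_subset_evaluated_twice(self, fake_world):
        reference, alignments, builder = fake_world
        cfg = SelectionConfig(rng_seed=0)
        result = random_subset_search(
            list("wxyz"), list("wxyz"), alignments, reference, cfg, builder
        )
        subsets = [r.subset for r in result.trace]
        assert len(subsets) == len(set(subsets))

    def test_constrained_to_current(self, six_leaf_trees):
        reference, _, _ = six_leaf_trees
        genes = [f"g{i}" for i in range(8)]
        alignments = {g: trivial_alignment(g, SPECIES) for g in genes}
        builder = MappingBuilder({}, default=reference)
        current = genes[:5]
        cfg = SelectionConfig(rng_seed=3, constrain_to_current=True)
        result = random_subset_search(
            genes, current, alignments, reference, cfg, builder
        )
        for rec in result.trace:
            assert set(rec.subset) <= set(current)

    def test_small_current_returns_unchanged(self, fake_world):
        reference, alignments, builder = fake_world
        cfg = SelectionConfig(rng_seed=0)
        result = random_subset_search(
            list("wxyz"), list("wx"), alignments, reference, cfg, builder
        )
        assert result.final_set == ("w", "x")
        assert result.termination == "exhausted"
        assert result.trace == ()

    def test_iteration_cap_without_qualifying(self, six_leaf_trees):
        reference, _, rf4 = six_leaf_trees
        genes = [f"g{i}" for i in range(10)]
        alignments = {g: trivial_alignment(g, SPECIES) for g in genes}
        builder = MappingBuilder({}, default=rf4)  # nothing ever qualifies
        cfg = SelectionConfig(rng_seed=1, max_random_iterations=30)
        result = random_subset_search(
            genes, genes, alignments, reference, cfg, builder
        )
        assert result.termination == "iteration_cap"
        assert len(result.trace) == 30
        assert result.final_set == tuple(sorted(genes))

    def test_restart_shrinks_further(self, six_leaf_trees):
        reference, _, _ = six_leaf_trees
        genes = [f"g{i}" for i in range(6)]
        alignments = {g: trivial_alignment(g, SPECIES) for g in genes}
        builder = MappingBuilder({}, default=reference)
        cfg = SelectionConfig(rng_seed=5, restart_rounds=3, max_random_iterations=40)
        result = random_subset_search(
            genes, genes, alignments, reference, cfg, builder
        )
        assert len(result.final_set) == 2


class TestExhaustiveSubsetSearch:
    def test_seven_genes_sizes_2_to_6(self, six_leaf_trees):
        reference, _, rf4 = six_leaf_trees
        genes = [f"g{i}" for i in range(7)]
        alignments = {g: trivial_alignment(g, SPECIES) for g in genes}
        builder = MappingBuilder({}, default=rf4)
        result = exhaustive_subset_search(
            genes, alignments, reference, SelectionConfig(), range(2, 7), builder
        )
        # C(7,2)+C(7,3)+C(7,4)+C(7,5)+C(7,6) = 21+35+35+21+7
        assert len(result.trace) == 119
        assert result.termination == "exhausted"
        assert result.final_set == tuple(sorted(genes))

    def test_three_genes_size_two(self, fake_world):
        reference, alignments, builder = fake_world
        result = exhaustive_subset_search(
            list("wxy"), alignments, reference, SelectionConfig(), [2], builder
        )
        assert len(result.trace) == 3
        assert result.termination == "found_smaller"
        assert len(result.final_set) == 2

    def test_budget_exceeded(self, fake_world):
        reference, alignments, builder = fake_world
        cfg = SelectionConfig(exhaustive_budget=2)
        with pytest.raises(SelectionError, match="random search"):
            exhaustive_subset_search(
                list("wxyz"), alignments, reference, cfg, [2], builder
            )

    def test_qualifying_but_not_selected_retained(self, fake_world):
        reference, alignments, builder = fake_world
        result = exhaustive_subset_search(
            list("wxyz"), alignments, reference, SelectionConfig(), [2, 3], builder
        )
        assert len(result.final_set) == 2
        # the size-3 qualifying subsets are still reported
        assert any(r.size == 3 for r in result.qualifying)


class TestSelectMinimalSet:
    def test_end_to_end_fake(self, fake_world):
        reference, alignments, builder = fake_world
        cfg = SelectionConfig(rng_seed=2)
        result = select_minimal_set(alignments, cfg, builder, reference)
        assert result.final_distance <= cfg.cutoff
        assert len(result.final_set) <= len(result.progressive.genes)

    def test_skip_minimization(self, fake_world):
        reference, alignments, builder = fake_world
        cfg = SelectionConfig(rng_seed=2)
        result = select_minimal_set(
            alignments, cfg, builder, reference, search="none"
        )
        assert set(result.final_set) == set(result.progressive.genes)
        assert result.search.termination == "skipped"

    def test_zero_iterations_skips(self, fake_world):
        reference, alignments, builder = fake_world
        cfg = SelectionConfig(rng_seed=2, max_random_iterations=0)
        result = select_minimal_set(alignments, cfg, builder, reference)
        assert set(result.final_set) == set(result.progressive.genes)

    def test_same_seed_same_result(self, benchmark_small):
        t_species = sorted(benchmark_small.t_set)
        alignments = {
            g: a.restrict(t_species)
            for g, a in benchmark_small.alignments.items()
        }
        cfg = SelectionConfig(rng_seed=9)
        r1 = select_minimal_set(alignments, cfg)
        r2 = select_minimal_set(alignments, cfg)
        assert r1.final_set == r2.final_set
        assert r1.search.trace == r2.search.trace

    def test_benchmark_final_set_concordant(self, benchmark_small):
        t_species = sorted(benchmark_small.t_set)
        alignments = {
            g: a.restrict(t_species)
            for g, a in benchmark_small.alignments.items()
        }
        result = select_minimal_set(alignments, SelectionConfig(rng_seed=1))
        assert result.final_distance == 0.0
        assert len(result.final_set) <= len(result.progressive.genes)

    def test_bad_search_mode(self, fake_world):
        reference, alignments, builder = fake_world
        with pytest.raises(SelectionError):
            select_minimal_set(
                alignments, SelectionConfig(), builder, reference, search="x"
            )
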