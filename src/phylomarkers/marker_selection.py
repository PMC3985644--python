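"""Ranking, progressive concatenation and subset-minimization of markers.

The selection procedure:

1. build a reference tree from the concatenation of all widespread genes
   (or accept one supplied by the user);
2. score each gene by the topological distance of its tree to the
   reference and rank genes by increasing distance;
3. concatenate top-ranked genes progressively (n = 2, 3, ...) until the
   concatenation tree reaches a distance cut-off (default 0) - the genes
   used form the *initial marker set* of size m;
4. minimize: randomly subsample subsets of size 2..m-1 (optionally
   constrained to the initial set), or exhaustively enumerate subsets of
   requested sizes, stopping when the candidate space is exhausted, a
   smaller qualifying subset is found (after a minimum number of draws),
   or an iteration cap is hit. Finding a smaller set can restart the
   search with that set as the new current set.

All randomness flows from a single seed; subsets are drawn without
repetition so exhaustion of the candidate space is decidable and no subset
appears twice in a trace.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from math import comb
from typing import Callable, Iterable, Mapping, Sequence

from .phylo_io import Alignment, Tree, concatenate_alignments
from .tree_build import NeighborJoiningBuilder
from .tree_compare import nodal_distance, rf_distance

__all__ = [
    "MarkerScore",
    "SelectionConfig",
    "SelectionError",
    "SelectionResult",
    "TraceRecord",
    "ProgressiveResult",
    "MinimalSetSelection",
    "tree_distance",
    "build_reference",
    "rank_markers",
    "progressive_concatenation",
    "random_subset_search",
    "exhaustive_subset_search",
    "select_minimal_set",
]

Builder = Callable[[Alignment], Tree]

MEASURES = ("rf", "nrf", "nodal")


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerScore:
    gene_id: str
    distance: float
    rank: int  # 1-based, ascending distance, ties by gene_id


@dataclass(frozen=True)
class SelectionConfig:
    measure: str = "rf"
    cutoff: float = 0.0
    start_n: int = 2
    max_random_iterations: int = 100
    restart_rounds: int = 0
    constrain_to_current: bool = False
    rng_seed: int = 0
    exhaustive_budget: int = 100_000

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise SelectionError(f"unknown measure {self.measure!r}")
        if self.cutoff < 0:
            raise SelectionError("cutoff must be >= 0")
        if self.start_n < 1:
            raise SelectionError("start_n must be >= 1")
        if self.max_random_iterations < 0:
            raise SelectionError("max_random_iterations must be >= 0")
        if self.restart_rounds < 0:
            raise SelectionError("restart_rounds must be >= 0")


@dataclass(frozen=True)
class TraceRecord:
    subset: tuple[str, ...]  # sorted gene ids
    size: int
    distance: float
    accepted: bool  # distance <= cutoff


@dataclass(frozen=True)
class SelectionResult:
    initial_set: tuple[str, ...]
    final_set: tuple[str, ...]
    trace: tuple[TraceRecord, ...]
    termination: str  # exhausted | found_smaller | iteration_cap | skipped
    rng_seed: int
    qualifying: tuple[TraceRecord, ...] = ()


@dataclass(frozen=True)
class ProgressiveResult:
    genes: tuple[str, ...]  # the initial marker set, in rank order
    converged: bool
    steps: tuple[tuple[int, float], ...]  # (n, distance) per concatenation


def tree_distance(tree: Tree, reference: Tree, measure: str = "rf") -> float:
    if measure == "rf":
        return float(rf_distance(tree, reference)[0])
    if measure == "nrf":
        return rf_distance(tree, reference)[1]
    if measure == "nodal":
        return nodal_distance(tree, reference)
    raise SelectionError(f"unknown measure {measure!r}")


def _as_dict(alignments: Mapping[str, Alignment] | Iterable[Alignment]) -> dict[str, Alignment]:
    if isinstance(alignments, Mapping):
        return dict(alignments)
    return {aln.gene_id: aln for aln in alignments}


class _SubsetEvaluator:
    """Builds and scores concatenation trees, memoizing by gene subset."""

    def __init__(
        self,
        alignments: Mapping[str, Alignment],
        reference: Tree,
        builder: Builder,
        measure: str,
    ) -> None:
        self.alignments = alignments
        self.reference = reference
        self.builder = builder
        self.measure = measure
        self.species = sorted(reference.leaves)
        self._memo: dict[frozenset[str], float] = {}

    def distance(self, genes: Iterable[str]) -> float:
        key = frozenset(genes)
        if key not in self._memo:
            alns = [
                self.alignments[g].restrict(self.species, fill_missing=True)
                for g in sorted(key)
            ]
            tree = self.builder(concatenate_alignments(alns))
            self._memo[key] = tree_distance(tree, self.reference, self.measure)
        return self._memo[key]


def build_reference(
    alignments: Mapping[str, Alignment] | Iterable[Alignment],
    builder: Builder | None = None,
) -> Tree:
    """Reference phylogeny from the concatenation of all alignments."""
    alignments = _as_dict(alignments)
    if not alignments:
        raise SelectionError("no alignments supplied")
    builder = builder or NeighborJoiningBuilder()
    supermatrix = concatenate_alignments(
        [alignments[g] for g in sorted(alignments)]
    )
    return builder(supermatrix)


def rank_markers(
    alignments: Mapping[str, Alignment] | Iterable[Alignment],
    reference: Tree,
    builder: Builder | None = None,
    measure: str = "rf",
) -> list[MarkerScore]:
    """Score each gene by the distance of its tree to the reference.

    Genes that do not cover the full reference leaf set are excluded with a
    warning. Ties are broken by gene id, ascending.
    """
    alignments = _as_dict(alignments)
    builder = builder or NeighborJoiningBuilder()
    ref_leaves = reference.leaves
    scored: list[tuple[str, float]] = []
    for gene_id in sorted(alignments):
        aln = alignments[gene_id]
        if not ref_leaves <= set(aln.species):
            warnings.warn(
                f"gene {gene_id} excluded from ranking: missing species "
                f"{sorted(ref_leaves - set(aln.species))}",
                stacklevel=2,
            )
            continue
        tree = builder(aln.restrict(sorted(ref_leaves)))
        scored.append((gene_id, tree_distance(tree, reference, measure)))
    if not scored:
        raise SelectionError("no scorable genes (all excluded)")
    scored.sort(key=lambda gd: (gd[1], gd[0]))
    return [
        MarkerScore(gene_id=g, distance=d, rank=i + 1)
        for i, (g, d) in enumerate(scored)
    ]


def progressive_concatenation(
    ranked: Sequence[MarkerScore],
    alignments: Mapping[str, Alignment] | Iterable[Alignment],
    reference: Tree,
    cfg: SelectionConfig,
    builder: Builder | None = None,
    evaluator: _SubsetEvaluator | None = None,
) -> ProgressiveResult:
    """Grow the initial marker set by concatenating top-ranked genes.

    Returns the smallest rank prefix (n >= cfg.start_n) whose concatenation
    tree is within the cut-off of the reference; if no prefix qualifies,
    all genes are returned flagged not-converged. Distances are evaluated
    at every step, never assumed monotone.
    """
    if not ranked:
        raise SelectionError("empty ranking")
    alignments = _as_dict(alignments)
    if evaluator is None:
        evaluator = _SubsetEvaluator(
            alignments, reference, builder or NeighborJoiningBuilder(), cfg.measure
        )
    order = [score.gene_id for score in ranked]
    steps: list[tuple[int, float]] = []
    for n in range(min(cfg.start_n, len(order)), len(order) + 1):
        distance = evaluator.distance(order[:n])
        steps.append((n, distance))
        if distance <= cfg.cutoff:
            return ProgressiveResult(tuple(order[:n]), True, tuple(steps))
    return ProgressiveResult(tuple(order), False, tuple(steps))


def _unseen_count(pool: Sequence[str], size: int, seen: set[frozenset[str]]) -> int:
    pool_set = set(pool)
    already = sum(
        1 for s in seen if len(s) == size and s <= pool_set
    )
    return comb(len(pool), size) - already


def _draw_unseen(
    pool: Sequence[str],
    size: int,
    seen: set[frozenset[str]],
    rng: random.Random,
    max_attempts: int = 200,
) -> frozenset[str]:
    for _ in range(max_attempts):
        subset = frozenset(rng.sample(list(pool), size))
        if subset not in seen:
            return subset
    # dense region: fall back to deterministic enumeration of unseen subsets
    from itertools import combinations

    for combo in combinations(sorted(pool), size):
        subset = frozenset(combo)
        if subset not in seen:
            return subset
    raise AssertionError("no unseen subset despite positive unseen count")


def random_subset_search(
    pool: Sequence[str],
    current: Sequence[str],
    alignments: Mapping[str, Alignment] | Iterable[Alignment],
    reference: Tree,
    cfg: SelectionConfig,
    builder: Builder | None = None,
    evaluator: _SubsetEvaluator | None = None,
) -> SelectionResult:
    """Minimize the current marker set by random subset sampling.

    Subset sizes are drawn uniformly over 2..m-1 (m = |current|), members
    uniformly within the pool; subsets are never evaluated twice. A round
    stops when the candidate space is exhausted, or after
    ``max_random_iterations`` evaluations (termination ``found_smaller`` if
    a qualifying smaller subset was seen, else ``iteration_cap``); a
    qualifying find is never acted on before the iteration minimum unless
    the space ran out first. With ``restart_rounds > 0`` a find restarts
    the search from the smaller set with the remaining restart budget. With
    ``constrain_to_current`` the pool is the current set itself.
    """
    alignments = _as_dict(alignments)
    pool = sorted(dict.fromkeys(pool))
    current = tuple(dict.fromkeys(current))
    if not cfg.constrain_to_current and not set(current) <= set(pool):
        raise SelectionError("current set must be contained in the pool")
    if evaluator is None:
        evaluator = _SubsetEvaluator(
            alignments, reference, builder or NeighborJoiningBuilder(), cfg.measure
        )
    rng = random.Random(cfg.rng_seed)
    trace: list[TraceRecord] = []
    qualifying: list[TraceRecord] = []
    seen: set[frozenset[str]] = set()
    initial = current
    rounds_left = cfg.restart_rounds
    termination = "exhausted"

    while True:
        m = len(current)
        if m < 3:
            break  # nothing to search below size 2
        round_pool = list(current) if cfg.constrain_to_current else list(pool)
        sizes = list(range(2, m))
        round_qualifying: list[TraceRecord] = []
        evaluated = 0
        while True:
            open_sizes = [
                k for k in sizes if _unseen_count(round_pool, k, seen) > 0
            ]
            if not open_sizes:
                termination = "exhausted"
                break
            if evaluated >= cfg.max_random_iterations:
                termination = (
                    "found_smaller" if round_qualifying else "iteration_cap"
                )
                break
            size = open_sizes[rng.randrange(len(open_sizes))]
            subset = _draw_unseen(round_pool, size, seen, rng)
            seen.add(subset)
            distance = evaluator.distance(subset)
            record = TraceRecord(
                tuple(sorted(subset)), size, distance, distance <= cfg.cutoff
            )
            trace.append(record)
            evaluated += 1
            if record.accepted:
                round_qualifying.append(record)
        qualifying.extend(round_qualifying)
        if round_qualifying and rounds_left > 0:
            best = min(
                round_qualifying, key=lambda r: (r.size, r.distance, r.subset)
            )
            current = best.subset
            rounds_left -= 1
            continue
        break

    if qualifying:
        best = min(qualifying, key=lambda r: (r.size, r.distance, r.subset))
        final = best.subset
    else:
        final = tuple(sorted(initial))
    return SelectionResult(
        initial_set=tuple(initial),
        final_set=final,
        trace=tuple(trace),
        termination=termination,
        rng_seed=cfg.rng_seed,
        qualifying=tuple(qualifying),
    )


def exhaustive_subset_search(
    current: Sequence[str],
    alignments: Mapping[str, Alignment] | Iterable[Alignment],
    reference: Tree,
    cfg: SelectionConfig,
    sizes: Iterable[int],
    builder: Builder | None = None,
    evaluator: _SubsetEvaluator | None = None,
) -> SelectionResult:
    """Evaluate every subset of the current set at the requested sizes.

    The final set is the smallest qualifying subset (ties: best distance,
    then lexicographic gene ids); all qualifying subsets are retained in
    the result so a larger set may still be chosen downstream on other
    grounds.
    """
    from itertools import combinations

    alignments = _as_dict(alignments)
    current_sorted = tuple(sorted(dict.fromkeys(current)))
    sizes = sorted(set(sizes))
    if any(k < 2 or k > len(current_sorted) for k in sizes):
        raise SelectionError(
            f"sizes must lie in [2, {len(current_sorted)}], got {sizes}"
        )
    total = sum(comb(len(current_sorted), k) for k in sizes)
    if total > cfg.exhaustive_budget:
        raise SelectionError(
            f"{total} subsets exceed the exhaustive budget "
            f"({cfg.exhaustive_budget}); use the random search instead"
        )
    if evaluator is None:
        evaluator = _SubsetEvaluator(
            alignments, reference, builder or NeighborJoiningBuilder(), cfg.measure
        )
    trace: list[TraceRecord] = []
    qualifying: list[TraceRecord] = []
    for k in sizes:
        for combo in combinations(current_sorted, k):
            distance = evaluator.distance(combo)
            record = TraceRecord(combo, k, distance, distance <= cfg.cutoff)
            trace.append(record)
            if record.accepted:
                qualifying.append(record)
    if qualifying:
        best = min(qualifying, key=lambda r: (r.size, r.distance, r.subset))
        final = best.subset
        termination = (
            "found_smaller" if best.size < len(current_sorted) else "exhausted"
        )
    else:
        final = current_sorted
        termination = "exhausted"
    return SelectionResult(
        initial_set=tuple(current),
        final_set=final,
        trace=tuple(trace),
        termination=termination,
        rng_seed=cfg.rng_seed,
        qualifying=tuple(qualifying),
    )


@dataclass(frozen=True)
class MinimalSetSelection:
    """Full output of the selection stage."""

    reference: Tree
    ranking: tuple[MarkerScore, ...]
    progressive: ProgressiveResult
    search: SelectionResult
    final_set: tuple[str, ...]
    final_distance: float


def select_minimal_set(
    alignments: Mapping[str, Alignment] | Iterable[Alignment],
    cfg: SelectionConfig,
    builder: Builder | None = None,
    reference: Tree | None = None,
    search: str = "random",
    exhaustive_sizes: Iterable[int] | None = None,
) -> MinimalSetSelection:
    """End-to-end selection: reference, ranking, growth, minimization.

    ``search`` is one of ``random``, ``exhaustive``, ``both`` (random then
    exhaustive on its result) or ``none``. Setting
    ``cfg.max_random_iterations = 0`` (or ``search='none'``) skips
    minimization, leaving the final set equal to the initial one. The final
    set's distance is re-evaluated after selection.
    """
    if search not in ("random", "exhaustive", "both", "none"):
        raise SelectionError(f"unknown search mode {search!r}")
    alignments = _as_dict(alignments)
    builder = builder or NeighborJoiningBuilder()
    if reference is None:
        reference = build_reference(alignments, builder)
    ranking = rank_markers(alignments, reference, builder, cfg.measure)
    evaluator = _SubsetEvaluator(alignments, reference, builder, cfg.measure)
    progressive = progressive_concatenation(
        ranking, alignments, reference, cfg, evaluator=evaluator
    )
    initial = progressive.genes
    ranked_ids = [s.gene_id for s in ranking]

    if search == "none" or cfg.max_random_iterations == 0 or not progressive.converged:
        result = SelectionResult(
            initial_set=initial,
            final_set=tuple(sorted(initial)),
            trace=(),
            termination="skipped",
            rng_seed=cfg.rng_seed,
        )
    elif search in ("random", "both"):
        result = random_subset_search(
            ranked_ids, initial, alignments, reference, cfg, evaluator=evaluator
        )
        if search == "both" and len(result.final_set) >= 2:
            sizes = exhaustive_sizes or range(
                2, max(2, len(result.final_set))
            )
            sizes = [k for k in sizes if 2 <= k <= len(result.final_set)]
            if sizes:
                exhaustive = exhaustive_subset_search(
                    result.final_set,
                    alignments,
                    reference,
                    cfg,
                    sizes,
                    evaluator=evaluator,
                )
                result = SelectionResult(
                    initial_set=initial,
                    final_set=exhaustive.final_set,
                    trace=result.trace + exhaustive.trace,
                    termination=exhaustive.termination,
                    rng_seed=cfg.rng_seed,
                    qualifying=result.qualifying + exhaustive.qualifying,
                )
    else:  # exhaustive only
        sizes = exhaustive_sizes or range(2, max(2, len(initial)))
        sizes = [k for k in sizes if 2 <= k <= len(initial)]
        result = exhaustive_subset_search(
            initial, alignments, reference, cfg, sizes, evaluator=evaluator
        )

    final = tuple(sorted(result.final_set))
    final_distance = evaluator.distance(final)
    return MinimalSetSelection(
        reference=reference,
        ranking=tuple(ranking),
        progressive=progressive,
        search=result,
        final_set=final,
        final_distance=final_distance,
    )
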