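"""Topological distances and certainty measures between trees.

All measures operate on bipartitions (splits): the two leaf subsets induced
by removing an internal edge of an unrooted tree. Robinson-Foulds is the
size of the symmetric difference of the two split sets; the normalized
variant divides by the total number of splits in both trees, so it equals
the fraction of wrong splits for binary trees. The internode-certainty /
tree-certainty scores weigh each reference split against its strongest
conflicting split observed across a gene-tree collection.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .phylo_io import Tree

__all__ = [
    "Bipartition",
    "CertaintyReport",
    "TreeComparisonError",
    "bipartition_set",
    "rf_distance",
    "nodal_distance",
    "tree_certainty",
    "restrict_to_common_leaves",
]


class TreeComparisonError(ValueError):
    """Raised when trees cannot be compared (e.g. leaf-set mismatch)."""


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of a leaf universe, stored canonically.

    ``side`` is the smaller of the two subsets (ties broken by lexicographic
    order of the sorted labels) so equal splits always compare equal.
    """

    side: frozenset[str]
    universe: frozenset[str]

    @classmethod
    def of(cls, side: Iterable[str], universe: Iterable[str]) -> "Bipartition":
        universe = frozenset(universe)
        side = frozenset(side)
        other = universe - side
        if not side <= universe:
            raise ValueError("side is not a subset of the universe")
        if len(side) < 2 or len(other) < 2:
            raise ValueError(f"trivial bipartition: |side|={len(side)}")
        key = lambda s: (len(s), tuple(sorted(s)))
        return cls(min(side, other, key=key), universe)

    @property
    def other_side(self) -> frozenset[str]:
        return self.universe - self.side

    def conflicts_with(self, other: "Bipartition") -> bool:
        """True if the two splits cannot co-occur in one tree.

        Splits A|B and C|D are compatible iff at least one of the four
        pairwise intersections is empty.
        """
        a, b = self.side, self.other_side
        c, d = other.side, other.other_side
        return bool(a & c) and bool(a & d) and bool(b & c) and bool(b & d)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Bipartition({{{','.join(sorted(self.side))}}})"


def bipartition_set(tree: Tree) -> frozenset[Bipartition]:
    """All non-trivial splits of a tree (one per internal edge).

    A binary unrooted tree over n leaves yields exactly n - 3 splits;
    trees with fewer than 4 leaves yield the empty set.
    """
    universe = tree.leaves
    if len(universe) < 4:
        return frozenset()
    splits = set()
    for _, _, side in tree.edge_leaf_sets():
        if 2 <= len(side) <= len(universe) - 2:
            splits.add(Bipartition.of(side, universe))
    return frozenset(splits)


def _check_same_leaves(t1: Tree, t2: Tree) -> None:
    if t1.leaves != t2.leaves:
        only1 = sorted(t1.leaves - t2.leaves)
        only2 = sorted(t2.leaves - t1.leaves)
        raise TreeComparisonError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )


def rf_distance(t1: Tree, t2: Tree) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalized form.

    Returns ``(rf, normalized)`` where ``rf = |S1 ^ S2|`` (symmetric
    difference of split sets) and ``normalized = rf / (|S1| + |S2|)``
    (0 when both trees have no non-trivial splits).
    """
    _check_same_leaves(t1, t2)
    s1, s2 = bipartition_set(t1), bipartition_set(t2)
    rf = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    return rf, (rf / denom if denom else 0.0)


def nodal_distance(t1: Tree, t2: Tree, variant: str = "l2") -> float:
    """Distance from differences in leaf-to-leaf topological path lengths.

    ``l2`` (default): sqrt of the sum of squared differences over unordered
    leaf pairs. ``l1``: sum of absolute differences.
    """
    if variant not in ("l1", "l2"):
        raise ValueError(f"unknown variant {variant!r}")
    _check_same_leaves(t1, t2)
    labels1, p1 = t1.topological_path_matrix()
    labels2, p2 = t2.topological_path_matrix()
    assert labels1 == labels2  # both sorted over the same leaf set
    import numpy as np

    diff = np.triu(p1 - p2, k=1)
    if variant == "l1":
        return float(np.abs(diff).sum())
    return float(math.sqrt((diff**2).sum()))


@dataclass(frozen=True)
class CertaintyReport:
    """Per-branch internode certainty and its sum over the reference tree."""

    per_branch: Mapping[Bipartition, float]
    tree_certainty: float


def _internode_certainty(f1: int, f2: int) -> float:
    if f1 == 0 and f2 == 0:
        return 0.0
    if f2 == 0:
        return 1.0
    if f1 == 0:
        # Reference split never observed but conflicted: the source scoring
        # scheme assumes splits drawn from the gene trees themselves, where
        # f1 >= 1; rather than invent semantics we score 0 and warn.
        warnings.warn(
            "reference split unobserved in all gene trees but conflicted; "
            "internode certainty set to 0",
            stacklevel=3,
        )
        return 0.0
    total = f1 + f2
    p1, p2 = f1 / total, f2 / total
    return 1.0 + p1 * math.log2(p1) + p2 * math.log2(p2)


def tree_certainty(reference: Tree, gene_trees: Sequence[Tree]) -> CertaintyReport:
    """Internode certainty of every reference split against a gene-tree set.

    For a reference split observed in ``f1`` gene trees whose strongest
    conflicting split is observed in ``f2`` gene trees,
    ``IC = 1 + p1*log2(p1) + p2*log2(p2)`` with ``p_k = f_k / (f1 + f2)``;
    IC is 1 for an observed, unconflicted split and 0 for a split neither
    observed nor conflicted. The tree certainty is the sum of IC over all
    reference splits.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise TreeComparisonError("empty gene-tree collection")
    for gt in gene_trees:
        _check_same_leaves(reference, gt)
    ref_splits = bipartition_set(reference)
    gene_split_sets = [bipartition_set(gt) for gt in gene_trees]
    split_counts: Counter[Bipartition] = Counter()
    for splits in gene_split_sets:
        split_counts.update(splits)
    per_branch: dict[Bipartition, float] = {}
    for ref_split in sorted(ref_splits, key=lambda b: tuple(sorted(b.side))):
        f1 = split_counts.get(ref_split, 0)
        f2 = max(
            (
                count
                for split, count in split_counts.items()
                if split.conflicts_with(ref_split)
            ),
            default=0,
        )
        per_branch[ref_split] = _internode_certainty(f1, f2)
    return CertaintyReport(per_branch, sum(per_branch.values()))


def restrict_to_common_leaves(t1: Tree, t2: Tree) -> tuple[Tree, Tree]:
    """Both trees pruned to their shared leaves (explicit helper; distance
    functions themselves refuse mismatched leaf sets)."""
    common = t1.leaves & t2.leaves
    if len(common) < 3:
        raise TreeComparisonError(
            f"only {len(common)} shared leaves; need at least 3"
        )
    return t1.restrict(common), t2.restrict(common)
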