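"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import pytest

from phylomarkers.phylo_io import (
    Alignment,
    ConcatenatedAlignment,
    Tree,
    parse_newick,
)


# ---------------------------------------------------------------------------
# Independent topology machinery (oracle side; deliberately does not reuse
# the package's Tree/bipartition code)
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(labels: list[str]) -> list[list[tuple]]:
    """All unrooted binary topologies over the labels, as edge lists.

    Nodes are label strings (leaves) or negative ints (internal). Built by
    sequential leaf addition: each new leaf can subdivide any existing edge.
    """
    assert len(labels) >= 3
    base = [(labels[0], -1), (labels[1], -1), (labels[2], -1)]
    trees = [base]
    next_internal = -2
    for leaf in labels[3:]:
        grown = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = next_internal
                new_edges = edges[:i] + edges[i + 1 :]
                new_edges += [(u, w), (w, v), (leaf, w)]
                grown.append(new_edges)
        next_internal -= 1
        trees = grown
    return trees


def oracle_splits(edges: list[tuple]) -> frozenset[frozenset[str]]:
    """Non-trivial splits of an edge-list tree, brute force.

    For every edge, the leaves on one side are collected by flood fill; the
    smaller (ties: lexicographically smaller) side is kept.
    """
    adj: dict[object, set] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    leaves = {n for n in adj if isinstance(n, str)}
    splits = set()
    for u, v in edges:
        side: set[object] = set()
        stack = [u]
        while stack:
            node = stack.pop()
            if node in side:
                continue
            side.add(node)
            stack.extend(n for n in adj[node] if not (node == u and n == v))
        leaf_side = frozenset(n for n in side if isinstance(n, str))
        other = frozenset(leaves - leaf_side)
        if len(leaf_side) < 2 or len(other) < 2:
            continue
        canonical = min(
            (leaf_side, other), key=lambda s: (len(s), tuple(sorted(s)))
        )
        splits.add(canonical)
    return frozenset(splits)


def oracle_rf(edges1: list[tuple], edges2: list[tuple]) -> int:
    return len(oracle_splits(edges1) ^ oracle_splits(edges2))


def edges_to_newick(edges: list[tuple]) -> str:
    """Serialize an edge-list topology (no branch lengths) to Newick."""
    adj: dict[object, list] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = next(n for n in adj if not isinstance(n, str))

    def render(node, parent) -> str:
        if isinstance(node, str):
            return node
        children = [render(c, node) for c in adj[node] if c != parent]
        return "(" + ",".join(sorted(children)) + ")"

    return "(" + ",".join(sorted(render(c, root) for c in adj[root])) + ");"


# ---------------------------------------------------------------------------
# Stub builder for selection-logic tests
# ---------------------------------------------------------------------------


class MappingBuilder:
    """A fake tree builder returning canned trees keyed by gene subset."""

    def __init__(self, trees_by_genes: dict[frozenset, Tree], default: Tree | None = None):
        self.trees_by_genes = dict(trees_by_genes)
        self.default = default
        self.calls: list[frozenset] = []

    def __call__(self, aln: Alignment) -> Tree:
        if isinstance(aln, ConcatenatedAlignment):
            key = frozenset(p.gene_id for p in aln.partitions)
        else:
            key = frozenset([aln.gene_id])
        self.calls.append(key)
        if key in self.trees_by_genes:
            return self.trees_by_genes[key]
        if self.default is not None:
            return self.default
        raise KeyError(f"no canned tree for {sorted(key)}")


def trivial_alignment(gene_id: str, species: list[str], length: int = 4) -> Alignment:
    return Alignment(gene_id, [(sp, "A" * length) for sp in species])


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def six_leaf_trees():
    """Reference plus trees at hand-verified RF distances 2 and 4."""
    reference = parse_newick("((A,B),((C,D),(E,F)));")
    rf2 = parse_newick("(((A,B),C),(D,(E,F)));")  # shares AB, EF
    rf4 = parse_newick("((A,B),((C,E),(D,F)));")  # shares AB only
    return reference, rf2, rf4


@pytest.fixture(scope="session")
def benchmark_small():
    """A small simulated benchmark reused across tests (read-only)."""
    from phylomarkers.simulate import SimulationConfig, synthesize_benchmark

    cfg = SimulationConfig(
        n_species=12,
        n_genes=10,
        n_concordant=4,
        gene_length_range=(800, 800),
        discordance_nni_range=(2, 5),
        rng_seed=42,
    )
    return synthesize_benchmark(cfg)
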