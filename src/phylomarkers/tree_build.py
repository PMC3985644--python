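"""Distance-based tree inference and the external ML engine contract.

The built-in inference path is classical Saitou-Nei neighbor joining on
protein distances (p or Poisson-corrected). It is deliberately simple and
fully deterministic so the selection pipeline can be exercised end to end
without external tools; production runs can delegate tree building to any
maximum-likelihood engine through :class:`ExternalEngineBuilder`.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .phylo_io import Alignment, Tree, read_newick

__all__ = [
    "DistanceMatrix",
    "protein_distance_matrix",
    "neighbor_joining",
    "NeighborJoiningBuilder",
    "ExternalEngineBuilder",
    "REFERENCE_ML_PROTOCOL",
]

#: Recommended settings for an external maximum-likelihood adapter, for runs
#: that need publication-grade trees instead of the built-in NJ:
#: amino-acid model chosen per gene by computing the likelihood of a BioNJ
#: starting topology under JTT, LG, WAG, Blosum62, MtREV, VT and Dayhoff,
#: keeping the two best by AIC, inferring an ML tree under each and keeping
#: the tree with the best likelihood; rate heterogeneity modelled with a
#: discrete gamma distribution (four categories) plus invariant sites;
#: NNI rearrangements for single-gene trees, SPR for concatenations.
REFERENCE_ML_PROTOCOL = {
    "models": ["JTT", "LG", "WAG", "Blosum62", "MtREV", "VT", "Dayhoff"],
    "model_selection": "AIC on BioNJ starting topology, two best refined",
    "rates": "gamma (4 categories) + invariant sites",
    "rearrangement": {"single_gene": "NNI", "concatenation": "SPR"},
}


@dataclass(frozen=True, eq=False)
class DistanceMatrix:
    """A symmetric pairwise distance matrix over labelled taxa.

    ``saturated_pairs`` records pairs whose distance was capped (saturated
    or incomparable sequences).
    """

    labels: tuple[str, ...]
    d: np.ndarray
    saturated_pairs: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        size = len(self.labels)
        if self.d.shape != (size, size):
            raise ValueError(f"matrix shape {self.d.shape} != ({size}, {size})")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.d < 0):
            raise ValueError("distance matrix contains negative entries")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


def _encode(aln: Alignment, species: tuple[str, ...]) -> np.ndarray:
    data = "".join(aln.get(sp) for sp in species)
    return np.frombuffer(data.encode("ascii"), dtype=np.uint8).reshape(
        len(species), aln.length
    )


def protein_distance_matrix(
    aln: Alignment,
    correction: str = "poisson",
    p_cap: float = 0.95,
    d_cap: float = 10.0,
) -> DistanceMatrix:
    """Pairwise protein distances with pairwise deletion of gaps/unknowns.

    ``correction='p'`` gives the raw mismatch fraction over compared columns;
    ``'poisson'`` gives ``-ln(1 - p)``. Pairs with ``p >= p_cap`` or with no
    comparable column are capped at ``d_cap`` and flagged as saturated.
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    species = tuple(sorted(aln.species))
    if len(species) < 2:
        raise ValueError("need at least 2 species for a distance matrix")
    mat = _encode(aln, species)
    valid = (mat != ord("-")) & (mat != ord("X"))
    size = len(species)
    d = np.zeros((size, size), dtype=float)
    saturated: set[frozenset[str]] = set()
    for i in range(size):
        for j in range(i + 1, size):
            both = valid[i] & valid[j]
            n_cols = int(both.sum())
            if n_cols == 0:
                dist = d_cap
                saturated.add(frozenset((species[i], species[j])))
            else:
                p = np.count_nonzero((mat[i] != mat[j]) & both) / n_cols
                if p >= p_cap:
                    dist = d_cap
                    saturated.add(frozenset((species[i], species[j])))
                elif correction == "p":
                    dist = p
                else:
                    dist = -np.log1p(-p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(species, d, frozenset(saturated))


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Classical Saitou-Nei neighbor joining.

    Returns an unrooted binary tree with branch lengths (negative estimates
    clamped to 0). Deterministic: taxa are processed in sorted label order
    and exact ties in the Q criterion are broken by joining the pair whose
    (representative label_i, label_j) is lexicographically smallest, where a
    cluster is represented by its smallest leaf label.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float)

    adj: dict[int, dict[int, float | None]] = {i: {} for i in range(len(labels))}
    leaf_map = {i: lab for i, lab in enumerate(labels)}
    nodes = list(range(len(labels)))  # tree node id of each active cluster
    reps = list(labels)  # representative label per active cluster
    next_id = len(labels)

    def add_edge(u: int, v: int, length: float) -> None:
        length = max(0.0, float(length))
        adj.setdefault(u, {})[v] = length
        adj.setdefault(v, {})[u] = length

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = d.sum(axis=1)
        q = (r - 2) * d - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        # q may be asymmetric at the last float bit; normalize tie pairs
        qmin = q.min()
        ties = {
            (min(int(i), int(j)), max(int(i), int(j)))
            for i, j in np.argwhere(q == qmin)
        }
        i, j = min(ties, key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        li = 0.5 * d[i, j] + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        new_node = next_id
        next_id += 1
        add_edge(new_node, nodes[i], li)
        add_edge(new_node, nodes[j], lj)
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        new_d = np.empty((r - 1, r - 1), dtype=float)
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        new_d[-1, -1] = 0.0
        d = new_d
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [new_node]
        reps = [reps[k] for k in keep] + [new_rep]

    center = next_id
    (a, b, c) = nodes
    add_edge(center, a, (d[0, 1] + d[0, 2] - d[1, 2]) / 2)
    add_edge(center, b, (d[0, 1] + d[1, 2] - d[0, 2]) / 2)
    add_edge(center, c, (d[0, 2] + d[1, 2] - d[0, 1]) / 2)
    return Tree(adj, leaf_map)


class NeighborJoiningBuilder:
    """Callable turning an alignment into an NJ tree; the default builder."""

    def __init__(
        self,
        correction: str = "poisson",
        p_cap: float = 0.95,
        d_cap: float = 10.0,
    ) -> None:
        self.correction = correction
        self.p_cap = p_cap
        self.d_cap = d_cap

    def __call__(self, aln: Alignment) -> Tree:
        dm = protein_distance_matrix(
            aln, correction=self.correction, p_cap=self.p_cap, d_cap=self.d_cap
        )
        return neighbor_joining(dm)

    def __repr__(self) -> str:  # pragma: no cover
        return f"NeighborJoiningBuilder(correction={self.correction!r})"


class ExternalEngineBuilder:
    """Delegate tree building to an external command.

    ``command_template`` must contain ``{alignment}`` and ``{tree}``
    placeholders, e.g. ``"mytool --in {alignment} --out {tree}"``. The
    command must write a Newick tree over exactly the alignment's species;
    anything else is an error. See :data:`REFERENCE_ML_PROTOCOL` for the
    recommended ML settings.
    """

    def __init__(self, command_template: str, timeout: float | None = None) -> None:
        if "{alignment}" not in command_template or "{tree}" not in command_template:
            raise ValueError(
                "command template must contain {alignment} and {tree} placeholders"
            )
        self.command_template = command_template
        self.timeout = timeout

    def __call__(self, aln: Alignment) -> Tree:
        with tempfile.TemporaryDirectory(prefix="phylomarkers_") as tmp:
            aln_path = Path(tmp) / "alignment.fasta"
            tree_path = Path(tmp) / "tree.nwk"
            aln.to_fasta(aln_path)
            cmd = self.command_template.format(alignment=aln_path, tree=tree_path)
            subprocess.run(
                shlex.split(cmd), check=True, timeout=self.timeout, capture_output=True
            )
            tree = read_newick(tree_path)
        expected = frozenset(aln.species)
        if tree.leaves != expected:
            raise ValueError(
                "external engine returned a tree over the wrong taxa: "
                f"missing {sorted(expected - tree.leaves)}, "
                f"extra {sorted(tree.leaves - expected)}"
            )
        return tree


def distance_matrix_from_tree(tree: Tree, topological: bool = False) -> DistanceMatrix:
    """Exact leaf-to-leaf path-length matrix of a tree (additive distances)."""
    labels = tree.leaf_labels
    node_of = {lab: n for n, lab in tree.leaf_nodes().items()}
    adj = tree.adjacency()
    size = len(labels)
    d = np.zeros((size, size), dtype=float)
    for i, lab in enumerate(labels):
        dist: dict[int, float] = {node_of[lab]: 0.0}
        frontier = [node_of[lab]]
        while frontier:
            nxt = []
            for u in frontier:
                for v, length in adj[u].items():
                    if v not in dist:
                        if not topological and length is None:
                            raise ValueError(
                                "tree lacks branch lengths; use topological=True"
                            )
                        dist[v] = dist[u] + (1.0 if topological else float(length))
                        nxt.append(v)
            frontier = nxt
        for j, lab2 in enumerate(labels):
            d[i, j] = dist[node_of[lab2]]
    d = (d + d.T) / 2
    return DistanceMatrix(labels, d)
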