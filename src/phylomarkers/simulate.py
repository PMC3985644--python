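"""Synthetic benchmark generator with planted ground truth.

Produces Yule species trees, gene alignments evolved under an equal-rates
20-state amino-acid model (concordant genes on the species tree, discordant
genes on NNI-perturbed copies), a stratified training/validation species
split, and synthetic BLAST-style hit tables with planted paralogs and
losses. Everything is deterministic per (config, seed).

The equal-rates model has a simple closed form used throughout the tests:
for a path of expected length t substitutions/site, the probability that
the two endpoint states differ is ``(19/20) * (1 - exp(-(20/19) t))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .phylo_io import AMINO_ACIDS, Alignment, HitRecord, Tree, write_newick

__all__ = [
    "SimulationConfig",
    "GeneTruth",
    "SimulatedDataset",
    "SyntheticHits",
    "yule_tree",
    "nni_perturb",
    "evolve_sequences",
    "expected_mismatch_fraction",
    "scale_tree_height",
    "floor_internal_branches",
    "synthesize_benchmark",
    "synthesize_hit_tables",
]

_N_STATES = 20
_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 24
    n_genes: int = 40
    n_concordant: int = 10
    gene_length_range: tuple[int, int] = (500, 1500)
    rate_gamma_shape: float = 6.0
    discordance_nni_range: tuple[int, int] = (1, 6)
    birth_rate: float = 1.0
    rng_seed: int = 0
    tv_split_fraction: float = 2 / 3
    #: the species tree is rescaled so the deepest root-to-tip path equals
    #: this many expected substitutions/site; None keeps raw waiting times
    #: (which grow like ln(n)/birth_rate and saturate amino-acid distances).
    tree_height: float | None = 0.6
    #: internal branches shorter than this (after rescaling) are raised to
    #: it, so every species-tree split is recoverable from finite genes.
    min_internal_branch: float = 0.03

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if not 0 <= self.n_concordant <= self.n_genes:
            raise ValueError("n_concordant must be in [0, n_genes]")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid gene_length_range")
        klo, khi = self.discordance_nni_range
        if klo < 0 or khi < klo:
            raise ValueError("invalid discordance_nni_range")
        if not 0.0 < self.tv_split_fraction < 1.0:
            raise ValueError("tv_split_fraction must be in (0, 1)")
        if self.birth_rate <= 0 or self.rate_gamma_shape <= 0:
            raise ValueError("birth_rate and rate_gamma_shape must be > 0")
        if self.tree_height is not None and self.tree_height <= 0:
            raise ValueError("tree_height must be > 0 (or None)")
        if self.min_internal_branch < 0:
            raise ValueError("min_internal_branch must be >= 0")


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    concordant: bool
    nni_moves: int
    rate: float
    tree: Tree
    paralog_genomes: frozenset[str] = frozenset()
    lost_genomes: frozenset[str] = frozenset()


@dataclass
class SimulatedDataset:
    species_tree: Tree
    t_set: frozenset[str]
    v_set: frozenset[str]
    alignments: dict[str, Alignment]
    truth: dict[str, GeneTruth]
    hit_tables: dict[str, "SyntheticHits"] = field(default_factory=dict)

    @property
    def species(self) -> frozenset[str]:
        return self.t_set | self.v_set

    def write(self, out_dir: str | Path) -> None:
        """Persist the dataset as plain-text files."""
        out = Path(out_dir)
        (out / "genes").mkdir(parents=True, exist_ok=True)
        write_newick(self.species_tree, out / "species_tree.nwk")
        for gene_id in sorted(self.alignments):
            self.alignments[gene_id].to_fasta(out / "genes" / f"{gene_id}.fasta")
        lines = ["species\tset"]
        lines += [f"{sp}\tT" for sp in sorted(self.t_set)]
        lines += [f"{sp}\tV" for sp in sorted(self.v_set)]
        (out / "tv_split.tsv").write_text("\n".join(lines) + "\n")
        rows = ["gene_id\tconcordant\tnni_moves\trate\tparalog_genomes\tlost_genomes"]
        for gene_id in sorted(self.truth):
            t = self.truth[gene_id]
            rows.append(
                f"{gene_id}\t{int(t.concordant)}\t{t.nni_moves}\t{t.rate:.6g}\t"
                f"{','.join(sorted(t.paralog_genomes))}\t"
                f"{','.join(sorted(t.lost_genomes))}"
            )
        (out / "truth.tsv").write_text("\n".join(rows) + "\n")
        if self.hit_tables:
            hits_dir = out / "hits"
            hits_dir.mkdir(exist_ok=True)
            for seed_sp, table in sorted(self.hit_tables.items()):
                table.write(
                    hits_dir / f"{seed_sp}.hits.tsv",
                    hits_dir / f"{seed_sp}.qlens.tsv",
                )


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------


def _yule_with_clades(
    n: int, birth_rate: float, seed: int
) -> tuple[Tree, tuple[frozenset[str], frozenset[str]]]:
    rng = np.random.default_rng(seed)
    root = 0
    next_id = 1
    # active lineages: (attach_node, start_time, clade 0/1)
    active: list[tuple[int, float, int]] = [(root, 0.0, 0), (root, 0.0, 1)]
    adj: dict[int, dict[int, float | None]] = {root: {}}
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += float(rng.exponential(1.0 / (birth_rate * k)))
        idx = int(rng.integers(k))
        parent, start, clade = active.pop(idx)
        node = next_id
        next_id += 1
        length = t - start
        adj.setdefault(node, {})[parent] = length
        adj[parent][node] = length
        active.append((node, t, clade))
        active.append((node, t, clade))
    # extend pendant edges past the last split so no leaf edge has length 0
    t_end = t + float(rng.exponential(1.0 / (birth_rate * n)))
    labels: dict[int, str] = {}
    clades: tuple[set[str], set[str]] = (set(), set())
    for i, (parent, start, clade) in enumerate(active):
        leaf = next_id
        next_id += 1
        length = t_end - start
        adj.setdefault(leaf, {})[parent] = length
        adj[parent][leaf] = length
        label = f"S{i + 1:02d}"
        labels[leaf] = label
        clades[clade].add(label)
    return Tree(adj, labels), (frozenset(clades[0]), frozenset(clades[1]))


def scale_tree_height(tree: Tree, height: float) -> Tree:
    """Rescale branch lengths so the deepest leaf-to-leaf half-path (the
    root-to-tip depth of the midpoint-rooted tree) equals ``height``."""
    from .tree_build import distance_matrix_from_tree

    dm = distance_matrix_from_tree(tree)
    deepest = float(dm.d.max()) / 2.0
    if deepest <= 0:
        raise ValueError("tree has zero depth; cannot rescale")
    factor = height / deepest
    adj = {
        u: {v: (None if l is None else l * factor) for v, l in nbrs.items()}
        for u, nbrs in tree.adjacency().items()
    }
    return Tree(adj, tree.leaf_nodes())


def floor_internal_branches(tree: Tree, minimum: float) -> Tree:
    """Raise internal branch lengths below ``minimum`` up to it."""
    adj = tree.adjacency()
    labels = tree.leaf_nodes()
    for u, v, length in tree.edges():
        if u in labels or v in labels or length is None:
            continue
        if length < minimum:
            adj[u][v] = adj[v][u] = minimum
    return Tree(adj, labels)


def yule_tree(
    n: int, birth_rate: float = 1.0, seed: int = 0, height: float | None = None
) -> Tree:
    """A pure-birth (Yule) tree with ``n`` leaves labelled S01..Sn.

    Branch lengths are exponential waiting times; pass ``height`` to
    rescale the deepest root-to-tip path to a fixed value. The tree is
    returned unrooted (the root is suppressed on construction).
    Deterministic per seed.
    """
    if n < 3:
        raise ValueError("need n >= 3 leaves")
    tree, _ = _yule_with_clades(n, birth_rate, seed)
    if height is not None:
        tree = scale_tree_height(tree, height)
    return tree


def nni_perturb(tree: Tree, k: int, seed: int = 0) -> Tree:
    """Apply ``k`` successive nearest-neighbor interchanges.

    Each move picks an internal edge uniformly at random and swaps one
    subtree from each endpoint. The leaf set is unchanged; the input must
    be binary.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not tree.is_binary():
        raise ValueError("NNI perturbation requires a binary tree")
    if tree.n_leaves < 4:
        raise ValueError("NNI perturbation requires >= 4 leaves")
    rng = np.random.default_rng(seed)
    adj = tree.adjacency()
    labels = tree.leaf_nodes()

    def internal_edges() -> list[tuple[int, int]]:
        return sorted(
            (u, v)
            for u in adj
            for v in adj[u]
            if u < v and u not in labels and v not in labels
        )

    for _ in range(k):
        edges = internal_edges()
        u, v = edges[int(rng.integers(len(edges)))]
        u_nbrs = sorted(x for x in adj[u] if x != v)
        v_nbrs = sorted(x for x in adj[v] if x != u)
        x = u_nbrs[1]  # subtree moved away from u (fixed choice)
        y = v_nbrs[int(rng.integers(2))]  # subtree moved away from v
        lx = adj[u].pop(x)
        adj[x].pop(u)
        ly = adj[v].pop(y)
        adj[y].pop(v)
        adj[u][y] = ly
        adj[y][u] = ly
        adj[v][x] = lx
        adj[x][v] = lx
    return Tree(adj, labels)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def expected_mismatch_fraction(t: float) -> float:
    """Closed-form mismatch probability of the equal-rates 20-state model."""
    k = _N_STATES
    return (k - 1) / k * (1.0 - math.exp(-k / (k - 1) * t))


def evolve_sequences(
    tree: Tree,
    length: int,
    rate_multiplier: float = 1.0,
    seed: int = 0,
    gene_id: str = "gene",
) -> Alignment:
    """Evolve a gap-free amino-acid alignment along a tree.

    The substitution process is the equal-rates 20-state model: along a
    branch of length b, each site changes to a uniformly chosen different
    state with probability ``expected_mismatch_fraction(b * rate_multiplier)``
    (the exact matrix-exponential form). The root sequence is uniform over
    the 20 states.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate_multiplier < 0:
        raise ValueError("rate_multiplier must be >= 0")
    if not tree.has_branch_lengths:
        raise ValueError("tree must have branch lengths to evolve sequences")
    rng = np.random.default_rng(seed)
    adj = tree.adjacency()
    labels = tree.leaf_nodes()
    root = min(adj)
    seqs: dict[int, np.ndarray] = {
        root: rng.integers(_N_STATES, size=length, dtype=np.int64)
    }
    stack = [root]
    visited = {root}
    while stack:
        node = stack.pop()
        for child in sorted(adj[node]):
            if child in visited:
                continue
            visited.add(child)
            branch = float(adj[node][child]) * rate_multiplier
            p_change = expected_mismatch_fraction(branch)
            seq = seqs[node].copy()
            if p_change > 0:
                mask = rng.random(length) < p_change
                n_changed = int(mask.sum())
                if n_changed:
                    # uniform over the 19 *other* states
                    offsets = rng.integers(1, _N_STATES, size=n_changed)
                    seq[mask] = (seq[mask] + offsets) % _N_STATES
            seqs[child] = seq
            stack.append(child)
    rows = [
        (label, _AA_BYTES[seqs[node]].tobytes().decode("ascii"))
        for node, label in sorted(labels.items(), key=lambda kv: kv[1])
    ]
    return Alignment(gene_id, rows)


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------


def _stratified_split(
    clades: tuple[frozenset[str], frozenset[str]],
    fraction: float,
    n_train: int,
    rng: np.random.Generator,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split species so both sets intersect each of the two root clades
    (where clade sizes permit) while hitting the global training count."""
    sizes = [len(c) for c in clades]
    t0 = int(round(fraction * sizes[0]))
    t0 = max(1 if sizes[0] > 1 else sizes[0], min(t0, sizes[0] - 1 if sizes[0] > 1 else sizes[0]))
    t1 = n_train - t0
    lo1 = 1 if sizes[1] > 1 else 0
    hi1 = sizes[1] - 1 if sizes[1] > 1 else sizes[1]
    if t1 < lo1 or t1 > hi1:
        t1 = max(lo1, min(t1, hi1))
        t0 = n_train - t1
    train: set[str] = set()
    for clade, count in zip(clades, (t0, t1)):
        members = sorted(clade)
        picked = rng.permutation(len(members))[:count]
        train.update(members[i] for i in picked)
    all_species = clades[0] | clades[1]
    return frozenset(train), frozenset(all_species - train)


def synthesize_benchmark(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a full benchmark: species tree, T/V split, gene alignments.

    Concordant genes (named first: g001..) evolve on the species tree;
    discordant genes evolve on NNI-perturbed copies. Per-gene rate
    multipliers are Gamma(shape, 1/shape) distributed (mean 1).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    tree_seed = int(rng.integers(2**31))
    species_tree, clades = _yule_with_clades(
        cfg.n_species, cfg.birth_rate, tree_seed
    )
    if cfg.tree_height is not None:
        species_tree = scale_tree_height(species_tree, cfg.tree_height)
    if cfg.min_internal_branch > 0:
        species_tree = floor_internal_branches(
            species_tree, cfg.min_internal_branch
        )
    n_train = int(round(cfg.tv_split_fraction * cfg.n_species))
    t_set, v_set = _stratified_split(clades, cfg.tv_split_fraction, n_train, rng)

    width = max(3, len(str(cfg.n_genes)))
    alignments: dict[str, Alignment] = {}
    truth: dict[str, GeneTruth] = {}
    lo, hi = cfg.gene_length_range
    klo, khi = cfg.discordance_nni_range
    for i in range(cfg.n_genes):
        gene_id = f"g{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        rate = float(rng.gamma(cfg.rate_gamma_shape, 1.0 / cfg.rate_gamma_shape))
        perturb_seed = int(rng.integers(2**31))
        evolve_seed = int(rng.integers(2**31))
        concordant = i < cfg.n_concordant
        if concordant:
            k = 0
            gene_tree = species_tree
        else:
            k = int(rng.integers(klo, khi + 1))
            gene_tree = nni_perturb(species_tree, k, seed=perturb_seed)
        alignments[gene_id] = evolve_sequences(
            gene_tree, length, rate_multiplier=rate, seed=evolve_seed, gene_id=gene_id
        )
        truth[gene_id] = GeneTruth(
            gene_id=gene_id,
            concordant=concordant,
            nni_moves=k,
            rate=rate,
            tree=gene_tree,
        )
    return SimulatedDataset(
        species_tree=species_tree,
        t_set=t_set,
        v_set=v_set,
        alignments=alignments,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticHits:
    """Planted BLAST-style hits for one seed species."""

    seed_species: str
    records: tuple[HitRecord, ...]
    rows: tuple[tuple, ...]  # raw 12-column tabular rows
    query_lengths: Mapping[str, int]

    def write(self, hits_path: str | Path, qlens_path: str | Path) -> None:
        lines = ["\t".join(str(f) for f in row) for row in self.rows]
        Path(hits_path).write_text("\n".join(lines) + ("\n" if lines else ""))
        qlines = [f"{q}\t{l}" for q, l in sorted(self.query_lengths.items())]
        Path(qlens_path).write_text("\n".join(qlines) + "\n")


def synthesize_hit_tables(
    ds: SimulatedDataset,
    paralog_rate: float = 0.0,
    loss_rate: float = 0.0,
    seed: int = 0,
    seed_species: str | None = None,
    genomes: Sequence[str] | None = None,
) -> SyntheticHits:
    """Plant a hit table exercising the single-copy/e-value/coverage filters.

    For each gene x genome a strong qualifying hit is emitted (e-value
    1e-50, coverage 0.9); with probability ``paralog_rate`` a second
    qualifying hit is added (single-copy violation) and with probability
    ``loss_rate`` the hit is omitted (absence). The dataset's truth is
    updated with the planted violations and the table is attached to
    ``ds.hit_tables``.
    """
    if not 0.0 <= paralog_rate < 1.0 or not 0.0 <= loss_rate < 1.0:
        raise ValueError("rates must be in [0, 1)")
    if seed_species is None:
        seed_species = min(ds.t_set)
    if genomes is None:
        genomes = sorted(ds.species - {seed_species})
    rng = np.random.default_rng(seed)
    records: list[HitRecord] = []
    rows: list[tuple] = []
    query_lengths: dict[str, int] = {}
    for gene_id in sorted(ds.alignments):
        qid = f"{seed_species}|{gene_id}"
        qlen = ds.alignments[gene_id].length
        query_lengths[qid] = qlen
        paralogs: set[str] = set()
        losses: set[str] = set()
        for genome in genomes:
            if rng.random() < loss_rate:
                losses.add(genome)
                continue
            qend = max(1, int(round(0.9 * qlen)))
            coverage = (qend - 1 + 1) / qlen
            target = f"{genome}|{gene_id}"
            records.append(
                HitRecord(qid, target, genome, 1e-50, coverage, 500.0)
            )
            rows.append(
                (qid, target, 99.0, qend, 1, 0, 1, qend, 1, qend, "1e-50", 500.0)
            )
            if rng.random() < paralog_rate:
                paralogs.add(genome)
                qend2 = max(1, int(round(0.8 * qlen)))
                target2 = f"{genome}|{gene_id}_p2"
                records.append(
                    HitRecord(qid, target2, genome, 1e-30, qend2 / qlen, 300.0)
                )
                rows.append(
                    (qid, target2, 80.0, qend2, 5, 1, 1, qend2, 1, qend2, "1e-30", 300.0)
                )
        ds.truth[gene_id] = replace(
            ds.truth[gene_id],
            paralog_genomes=frozenset(paralogs),
            lost_genomes=frozenset(losses),
        )
    table = SyntheticHits(
        seed_species=seed_species,
        records=tuple(records),
        rows=tuple(rows),
        query_lengths=query_lengths,
    )
    ds.hit_tables[seed_species] = table
    return table
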