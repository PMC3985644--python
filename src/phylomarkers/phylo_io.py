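"""Core data structures and file formats for the marker-selection pipeline.

This module owns the unrooted :class:`Tree`, the :class:`Alignment` and its
partition-tracked concatenation, BLAST tabular hit records, and readers and
writers for Newick, aligned FASTA and hit tables.

Trees are always treated as unrooted: a degree-2 root present in the input
is collapsed on construction, since all downstream comparisons operate on
bipartitions, which are root-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import dendropy
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_ALLOWED_CHARS = frozenset(AMINO_ACIDS + GAP + UNKNOWN)
# Ambiguity / rare codes mapped to X on read; '.' is an alternative gap.
_RESIDUE_FIXUPS = str.maketrans({c: "X" for c in "BZJUO*"} | {".": "-"})


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate species...)."""


class HitTableError(ValueError):
    """Raised for malformed BLAST tabular input."""


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


class Tree:
    """An unrooted, leaf-labelled phylogeny with optional branch lengths.

    Parameters
    ----------
    adjacency
        ``{node: {neighbour: branch_length_or_None}}``; symmetric.
    labels
        ``{leaf_node: species_label}``. Leaf labels must be unique,
        non-empty strings.

    Degree-2 (rooting) nodes are suppressed on construction, merging the two
    incident branch lengths. After that every unlabelled node must have
    degree >= 3 and every labelled node degree <= 1.
    """

    __slots__ = ("_adj", "_labels", "_label_to_node")

    def __init__(
        self,
        adjacency: Mapping[int, Mapping[int, float | None]],
        labels: Mapping[int, str],
    ) -> None:
        self._adj: dict[int, dict[int, float | None]] = {
            u: dict(nbrs) for u, nbrs in adjacency.items()
        }
        self._labels: dict[int, str] = dict(labels)
        self._suppress_degree_two()
        self._validate()
        self._label_to_node = {lab: n for n, lab in self._labels.items()}

    # -- construction helpers -------------------------------------------------

    def _suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            for u in list(self._adj):
                if u not in self._adj or u in self._labels:
                    continue
                nbrs = self._adj[u]
                if len(nbrs) == 2:
                    (a, la), (b, lb) = nbrs.items()
                    if la is None and lb is None:
                        merged: float | None = None
                    else:
                        merged = (la or 0.0) + (lb or 0.0)
                    del self._adj[u]
                    del self._adj[a][u]
                    del self._adj[b][u]
                    self._adj[a][b] = merged
                    self._adj[b][a] = merged
                    changed = True
                elif len(nbrs) == 0 and len(self._adj) > 1:
                    del self._adj[u]
                    changed = True

    def _validate(self) -> None:
        if not self._labels:
            raise NewickError("tree has no labelled leaves")
        seen: set[str] = set()
        for node, lab in self._labels.items():
            if not isinstance(lab, str) or not lab:
                raise NewickError(f"empty leaf label at node {node}")
            if lab in seen:
                raise NewickError(f"duplicate leaf label {lab!r}")
            seen.add(lab)
            if node not in self._adj:
                raise NewickError(f"labelled node {node} missing from adjacency")
        for u, nbrs in self._adj.items():
            for v, length in nbrs.items():
                if self._adj.get(v, {}).get(u, "missing") != length:
                    raise NewickError(f"asymmetric adjacency at edge ({u}, {v})")
                if length is not None and length < 0:
                    raise NewickError(
                        f"negative branch length {length} on edge ({u}, {v})"
                    )
            if u not in self._labels and len(nbrs) < 3 and len(self._adj) > 2:
                raise NewickError(f"internal node {u} has degree {len(nbrs)} < 3")
            if u in self._labels and len(nbrs) > 1:
                raise NewickError(f"leaf node {u} has degree {len(nbrs)} > 1")

    # -- basic queries --------------------------------------------------------

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(self._labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        """Leaf labels in sorted order."""
        return tuple(sorted(self._labels.values()))

    @property
    def has_branch_lengths(self) -> bool:
        return all(
            l is not None for u, nbrs in self._adj.items() for l in nbrs.values()
        )

    def adjacency(self) -> dict[int, dict[int, float | None]]:
        """Deep copy of the internal adjacency map."""
        return {u: dict(nbrs) for u, nbrs in self._adj.items()}

    def leaf_nodes(self) -> dict[int, str]:
        """Copy of the node-id -> label map."""
        return dict(self._labels)

    def edges(self) -> Iterator[tuple[int, int, float | None]]:
        """Yield each undirected edge once as ``(u, v, length)`` with u < v."""
        for u in sorted(self._adj):
            for v in sorted(self._adj[u]):
                if u < v:
                    yield u, v, self._adj[u][v]

    def internal_edges(self) -> list[tuple[int, int]]:
        """Edges whose both endpoints are internal (unlabelled) nodes."""
        return [
            (u, v)
            for u, v, _ in self.edges()
            if u not in self._labels and v not in self._labels
        ]

    def is_binary(self) -> bool:
        return all(
            len(nbrs) == 3 for u, nbrs in self._adj.items() if u not in self._labels
        )

    def copy(self) -> "Tree":
        return Tree(self._adj, self._labels)

    # -- structural computations ---------------------------------------------

    def edge_leaf_sets(self) -> list[tuple[int, int, frozenset[str]]]:
        """For every edge ``(u, v)``, the leaf set on the ``v`` side.

        The tree is rooted (for traversal only) at the lowest node id;
        ``u`` is always the endpoint nearer that root.
        """
        if len(self._adj) <= 1:
            return []
        root = min(self._adj)
        order: list[tuple[int, int]] = []  # (parent, child)
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            if parent != -1:
                order.append((parent, node))
            for nbr in sorted(self._adj[node]):
                if nbr != parent:
                    stack.append((nbr, node))
        below: dict[int, set[str]] = {
            n: ({self._labels[n]} if n in self._labels else set())
            for n in self._adj
        }
        for parent, child in reversed(order):
            below[parent].update(below[child])
        return [(p, c, frozenset(below[c])) for p, c in order]

    def topological_path_matrix(self) -> tuple[tuple[str, ...], "np.ndarray"]:
        """Leaf-to-leaf path lengths counted in edges.

        Returns ``(labels, matrix)`` with labels in sorted order.
        """
        import numpy as np

        labels = self.leaf_labels
        node_of = {lab: n for n, lab in self._labels.items()}
        size = len(labels)
        mat = np.zeros((size, size), dtype=float)
        for i, lab in enumerate(labels):
            dist = {node_of[lab]: 0}
            frontier = [node_of[lab]]
            while frontier:
                nxt: list[int] = []
                for u in frontier:
                    for v in self._adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            for j, lab2 in enumerate(labels):
                mat[i, j] = dist[node_of[lab2]]
        return labels, mat

    def restrict(self, keep: Iterable[str]) -> "Tree":
        """The induced subtree over ``keep`` (degree-2 nodes suppressed)."""
        keep = set(keep)
        missing = keep - self.leaves
        if missing:
            raise NewickError(
                f"cannot restrict to absent leaves: {sorted(missing)}"
            )
        if not keep:
            raise NewickError("cannot restrict to an empty leaf set")
        adj = self.adjacency()
        labels = {n: lab for n, lab in self._labels.items() if lab in keep}
        doomed = [n for n, lab in self._labels.items() if lab not in keep]
        while doomed:
            u = doomed.pop()
            for v in list(adj[u]):
                del adj[v][u]
                if len(adj[v]) == 1 and v not in labels:
                    doomed.append(v)
            del adj[u]
        return Tree(adj, labels)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree(n_leaves={self.n_leaves})"


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into an (unrooted) :class:`Tree`.

    Raises :class:`NewickError` naming the offending position for unbalanced
    parentheses, duplicate leaf labels, or empty labels.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("Newick statement must be terminated by ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataParseError types
        raise NewickError(f"Newick parse error: {exc}") from exc
    ids: dict[object, int] = {}
    adj: dict[int, dict[int, float | None]] = {}
    labels: dict[int, str] = {}
    for node in dtree.preorder_node_iter():
        nid = ids.setdefault(node, len(ids))
        adj.setdefault(nid, {})
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else None
            if not label:
                raise NewickError("empty leaf label in Newick input")
            labels[nid] = label
        if node.parent_node is not None:
            pid = ids[node.parent_node]
            length = node.edge.length
            if length is not None and length < 0:
                raise NewickError(
                    f"negative branch length {length} for node {labels.get(nid, nid)}"
                )
            adj[pid][nid] = length
            adj[nid][pid] = length
    return Tree(adj, labels)


_UNSAFE_LABEL_CHARS = set("()[]{}:;,'\" \t\n")


def _format_label(label: str) -> str:
    if set(label) & _UNSAFE_LABEL_CHARS:
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(length: float | None) -> str:
    return "" if length is None else f":{length:.10g}"


def write_newick(tree: Tree, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick. Round-trips split sets and branch lengths.

    Children are ordered by the smallest leaf label in their subtree so the
    output is deterministic regardless of internal node numbering.
    """
    adj = tree.adjacency()
    labels = tree.leaf_nodes()
    if len(adj) == 1:
        text = f"{_format_label(next(iter(labels.values())))};"
    else:
        internal = sorted(n for n in adj if n not in labels)
        if internal:
            # root the display at the internal node adjacent to the
            # smallest leaf label, so equal trees serialize identically
            # regardless of internal node numbering
            first_leaf = min(labels, key=labels.get)
            root = next(iter(adj[first_leaf]))
        else:  # two-leaf tree: synthesize a display root on the single edge
            (a, b, length), = list(tree.edges())
            la, lb = labels[a], labels[b]
            text = (
                f"({_format_label(min(la, lb))},"
                f"{_format_label(max(la, lb))}{_format_length(length)});"
            )
            if path is not None:
                Path(path).write_text(text + "\n")
            return text

        def render(node: int, parent: int) -> tuple[str, str]:
            if node in labels:
                body, lowest = _format_label(labels[node]), labels[node]
            else:
                parts = [render(c, node) for c in adj[node] if c != parent]
                parts.sort(key=lambda p: p[1])
                body = "(" + ",".join(p[0] for p in parts) + ")"
                lowest = min(p[1] for p in parts)
            return body + _format_length(adj[parent][node]), lowest

        parts = [render(c, root) for c in adj[root]]
        parts.sort(key=lambda p: p[1])
        text = "(" + ",".join(p[0] for p in parts) + ");"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(path: str | Path) -> Tree:
    return parse_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


class Alignment:
    """A fixed-length amino-acid multiple sequence alignment for one gene.

    Rows are ordered ``(species_label, sequence)`` pairs; sequences use the
    20 IUPAC one-letter codes plus ``-`` (gap) and ``X`` (unknown).
    """

    __slots__ = ("gene_id", "_rows", "_index")

    def __init__(self, gene_id: str, rows: Iterable[tuple[str, str]]) -> None:
        self.gene_id = gene_id
        self._rows: tuple[tuple[str, str], ...] = tuple(
            (sp, seq) for sp, seq in rows
        )
        if not self._rows:
            raise AlignmentError(f"{gene_id}: alignment has no rows")
        length = len(self._rows[0][1])
        seen: set[str] = set()
        for sp, seq in self._rows:
            if sp in seen:
                raise AlignmentError(f"{gene_id}: duplicate species {sp!r}")
            seen.add(sp)
            if len(seq) != length:
                raise AlignmentError(
                    f"{gene_id}: not aligned - row {sp!r} has length "
                    f"{len(seq)}, expected {length}"
                )
            bad = set(seq) - _ALLOWED_CHARS
            if bad:
                raise AlignmentError(
                    f"{gene_id}: invalid residue(s) {sorted(bad)} in row {sp!r}"
                )
        self._index = {sp: seq for sp, seq in self._rows}

    @property
    def rows(self) -> tuple[tuple[str, str], ...]:
        return self._rows

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sp for sp, _ in self._rows)

    @property
    def length(self) -> int:
        return len(self._rows[0][1])

    @property
    def n_species(self) -> int:
        return len(self._rows)

    def __contains__(self, species: str) -> bool:
        return species in self._index

    def get(self, species: str) -> str:
        return self._index[species]

    def restrict(
        self, species: Iterable[str], *, fill_missing: bool = False
    ) -> "Alignment":
        """Rows for ``species`` only; optionally gap-fill absent species."""
        wanted = list(species)
        rows: list[tuple[str, str]] = []
        for sp in wanted:
            if sp in self._index:
                rows.append((sp, self._index[sp]))
            elif fill_missing:
                rows.append((sp, GAP * self.length))
            else:
                raise AlignmentError(
                    f"{self.gene_id}: species {sp!r} absent from alignment"
                )
        return Alignment(self.gene_id, rows)

    def to_fasta(self, path: str | Path | None = None, width: int = 60) -> str:
        chunks: list[str] = []
        for sp, seq in self._rows:
            chunks.append(f">{sp}")
            chunks.extend(seq[i : i + width] for i in range(0, len(seq), width))
        text = "\n".join(chunks) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Alignment({self.gene_id!r}, n_species={self.n_species}, "
            f"length={self.length})"
        )


@dataclass(frozen=True)
class Partition:
    """1-based inclusive column span of one gene in a supermatrix."""

    gene_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ConcatenatedAlignment(Alignment):
    """A supermatrix with a partition map from columns back to genes."""

    __slots__ = ("partitions",)

    def __init__(
        self,
        rows: Iterable[tuple[str, str]],
        partitions: Sequence[Partition],
        gene_id: str = "concatenation",
    ) -> None:
        super().__init__(gene_id, rows)
        self.partitions: tuple[Partition, ...] = tuple(partitions)
        pos = 1
        for part in self.partitions:
            if part.start != pos or part.end < part.start:
                raise AlignmentError(
                    f"partitions do not tile the supermatrix at {part}"
                )
            pos = part.end + 1
        if pos - 1 != self.length:
            raise AlignmentError(
                f"partition span {pos - 1} != alignment length {self.length}"
            )

    def extract(self, gene_id: str) -> Alignment:
        """Recover one gene's alignment; species with all-gap blocks drop out."""
        for part in self.partitions:
            if part.gene_id == gene_id:
                rows = []
                for sp, seq in self.rows:
                    block = seq[part.start - 1 : part.end]
                    if set(block) != {GAP}:
                        rows.append((sp, block))
                return Alignment(gene_id, rows)
        raise KeyError(f"no partition named {gene_id!r}")

    def partition_tsv(self, path: str | Path | None = None) -> str:
        lines = ["gene_id\tstart\tend"]
        lines += [f"{p.gene_id}\t{p.start}\t{p.end}" for p in self.partitions]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def raxml_partitions(self, path: str | Path | None = None) -> str:
        text = (
            "\n".join(
                f"PROT, {p.gene_id} = {p.start}-{p.end}" for p in self.partitions
            )
            + "\n"
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def read_fasta_alignment(path: str | Path, gene_id: str | None = None) -> Alignment:
    """Read an aligned FASTA file; headers are species labels (first token).

    Residues are upper-cased; ambiguity codes (B, Z, J, U, O, ``*``) become
    ``X`` and ``.`` becomes a gap.
    """
    path = Path(path)
    if gene_id is None:
        gene_id = path.stem
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        species = record.id.split()[0]
        if species in seen:
            raise AlignmentError(f"{path}: duplicate header {species!r}")
        seen.add(species)
        seq = str(record.seq).upper().translate(_RESIDUE_FIXUPS)
        rows.append((species, seq))
    if not rows:
        raise AlignmentError(f"{path}: no FASTA records")
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) > 1:
        raise AlignmentError(
            f"{path}: not aligned - row lengths {sorted(lengths)} differ"
        )
    return Alignment(gene_id, rows)


def concatenate_alignments(
    alignments: Sequence[Alignment],
    species: Iterable[str] | None = None,
) -> ConcatenatedAlignment:
    """Join per-gene alignments side by side into a supermatrix.

    Missing (species x gene) blocks are filled with gaps. Row order is the
    sorted species union (or the explicitly requested set).
    """
    alignments = list(alignments)
    if not alignments:
        raise AlignmentError("cannot concatenate an empty collection")
    present: set[str] = set()
    for aln in alignments:
        present.update(aln.species)
    if species is None:
        wanted = sorted(present)
    else:
        wanted = sorted(set(species))
        orphans = set(wanted) - present
        if orphans:
            warnings.warn(
                f"species absent from every alignment get all-gap rows: "
                f"{sorted(orphans)}",
                stacklevel=2,
            )
    parts: list[Partition] = []
    pos = 1
    for aln in alignments:
        parts.append(Partition(aln.gene_id, pos, pos + aln.length - 1))
        pos += aln.length
    rows = []
    for sp in wanted:
        chunks = [
            aln.get(sp) if sp in aln else GAP * aln.length for aln in alignments
        ]
        rows.append((sp, "".join(chunks)))
    return ConcatenatedAlignment(rows, parts)


# ---------------------------------------------------------------------------
# BLAST tabular hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One BLAST hit with genome attribution and derived query coverage."""

    query_id: str
    target_id: str
    target_genome: str
    e_value: float
    query_coverage: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise HitTableError(f"negative e-value {self.e_value}")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise HitTableError(
                f"query coverage {self.query_coverage} outside [0, 1]"
            )


def _load_query_lengths(source: Mapping[str, int] | str | Path) -> Mapping[str, int]:
    if isinstance(source, Mapping):
        return source
    path = Path(source)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return {
            rec.id.split()[0]: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
    lengths: dict[str, int] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, value = line.split("\t")[:2]
        lengths[name] = int(value)
    return lengths


def default_genome_resolver(target_id: str) -> str:
    """Resolve the genome of a hit from a ``GENOME|protein`` target id."""
    if "|" not in target_id:
        raise HitTableError(
            f"cannot resolve genome for target {target_id!r}: no '|' separator "
            "and no explicit genome mapping supplied"
        )
    return target_id.split("|", 1)[0]


def read_hit_table(
    path: str | Path,
    query_lengths: Mapping[str, int] | str | Path,
    genome: str | None = None,
    genome_resolver: Callable[[str], str] | None = None,
) -> list[HitRecord]:
    """Read a 12-column BLAST tabular file (outfmt 6) into hit records.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Query coverage is computed as the aligned
    query span divided by the query length (``query_lengths`` maps query id
    to length, or points at a 2-column TSV / FASTA of the queries). The
    genome of each hit comes from ``genome`` (whole file), the
    ``genome_resolver`` callable, or the ``GENOME|protein`` convention.
    """
    lengths = _load_query_lengths(query_lengths)
    if genome_resolver is None:
        genome_resolver = default_genome_resolver
    records: list[HitRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise HitTableError(
                f"{path}:{lineno}: expected 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        qseqid, sseqid = fields[0], fields[1]
        try:
            qstart, qend = int(fields[6]), int(fields[7])
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise HitTableError(f"{path}:{lineno}: {exc}") from exc
        if evalue < 0:
            raise HitTableError(f"{path}:{lineno}: negative e-value {evalue}")
        if qseqid not in lengths:
            raise HitTableError(
                f"{path}:{lineno}: no query length known for {qseqid!r}"
            )
        coverage = min(1.0, (abs(qend - qstart) + 1) / lengths[qseqid])
        records.append(
            HitRecord(
                query_id=qseqid,
                target_id=sseqid,
                target_genome=genome if genome is not None else genome_resolver(sseqid),
                e_value=evalue,
                query_coverage=coverage,
                bit_score=bitscore,
            )
        )
    return records
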