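"""Selection of widespread single-copy genes from seed-species hit tables.

A seed protein qualifies as a widespread single-copy gene when, after
discarding hits that fail the e-value or query-coverage cut-offs, it has at
most one surviving target protein in every genome and exactly one in at
least a configurable fraction of the genomes. Searches from several seed
species can be merged by union or intersection of their ortholog groups.

Notes on the filter semantics:

* coverage is query coverage; multiple HSPs for a query-target pair are not
  merged (a target survives if any single HSP passes both cut-offs);
* "single copy" counts distinct surviving target proteins per genome, not
  HSPs;
* hits to the seed's own genome are ignored - the seed protein represents
  its own genome;
* the search is one-directional (no reciprocal-best check).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .phylo_io import HitRecord

__all__ = [
    "OrthologGroup",
    "OrthologyConfig",
    "OrthologyError",
    "single_copy_from_seed",
    "merge_seed_groups",
    "write_group_table",
]


class OrthologyError(ValueError):
    pass


@dataclass(frozen=True)
class OrthologGroup:
    """A widespread single-copy gene: one member protein per species."""

    gene_id: str
    seed: str
    members: Mapping[str, str]  # species label -> member protein id

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise OrthologyError(
                f"group {self.gene_id}: seed species {self.seed!r} not represented"
            )

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.members)

    def coincides_with(self, other: "OrthologGroup") -> bool:
        """Identity rule for cross-seed deduplication: the member maps agree
        on every species both groups cover."""
        shared = self.species & other.species
        return all(self.members[sp] == other.members[sp] for sp in shared)


@dataclass(frozen=True)
class OrthologyConfig:
    e_value_max: float = 1e-5
    min_coverage: float = 0.5
    min_species_fraction: float = 1.0
    merge_mode: str = "union"

    def __post_init__(self) -> None:
        if self.e_value_max < 0:
            raise OrthologyError("e_value_max must be >= 0")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise OrthologyError("min_coverage must be in [0, 1]")
        if not 0.0 < self.min_species_fraction <= 1.0:
            raise OrthologyError("min_species_fraction must be in (0, 1]")
        if self.merge_mode not in ("union", "intersection"):
            raise OrthologyError(f"unknown merge mode {self.merge_mode!r}")


def single_copy_from_seed(
    seed: str,
    hits: Iterable[HitRecord],
    genomes: Iterable[str],
    cfg: OrthologyConfig | None = None,
) -> list[OrthologGroup]:
    """Widespread single-copy genes detected from one seed species.

    ``genomes`` is the set of searched genomes excluding the seed itself. A
    query qualifies iff every genome has at most one surviving target and at
    least ``ceil(min_species_fraction * len(genomes))`` genomes have exactly
    one. Groups map each covered genome to its single member and the seed
    species to the query protein itself.
    """
    cfg = cfg or OrthologyConfig()
    genomes = set(genomes)
    if not genomes:
        raise OrthologyError("empty genome set")
    genomes.discard(seed)
    if not genomes:
        raise OrthologyError("genome set contains only the seed species")

    # query -> genome -> surviving target ids
    surviving: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    queries: set[str] = set()
    for hit in hits:
        if hit.target_genome == seed:
            continue  # self-genome hits are ignored
        if hit.target_genome not in genomes:
            raise OrthologyError(
                f"hit {hit.query_id} -> {hit.target_id}: unknown genome "
                f"{hit.target_genome!r}"
            )
        queries.add(hit.query_id)
        if hit.e_value <= cfg.e_value_max and hit.query_coverage >= cfg.min_coverage:
            surviving[hit.query_id][hit.target_genome].add(hit.target_id)

    required = math.ceil(cfg.min_species_fraction * len(genomes))
    groups: list[OrthologGroup] = []
    for query in sorted(queries):
        per_genome = surviving.get(query, {})
        if any(len(targets) > 1 for targets in per_genome.values()):
            continue  # a paralogous genome disqualifies the gene outright
        covered = {g: next(iter(t)) for g, t in per_genome.items() if len(t) == 1}
        if len(covered) < required:
            continue
        members = dict(covered)
        members[seed] = query
        groups.append(OrthologGroup(gene_id=query, seed=seed, members=members))
    return groups


def merge_seed_groups(
    per_seed: Mapping[str, Sequence[OrthologGroup]],
    mode: str = "union",
) -> list[OrthologGroup]:
    """Merge ortholog groups found from several seed species.

    Groups from different seeds are deemed identical when their member maps
    coincide on all shared species. ``union`` returns the deduplicated
    groups from all seeds; ``intersection`` only those recovered from every
    seed. Deduplication keeps the lexicographically smallest gene id.
    """
    if mode not in ("union", "intersection"):
        raise OrthologyError(f"unknown merge mode {mode!r}")
    if not per_seed:
        raise OrthologyError("no seeds provided")

    @dataclass
    class _Cluster:
        representative: OrthologGroup
        members: dict[str, str]
        seeds: set[str]

    clusters: list[_Cluster] = []
    flat = [
        group
        for seed in sorted(per_seed)
        for group in sorted(per_seed[seed], key=lambda g: g.gene_id)
    ]
    for group in flat:
        placed = False
        for cluster in clusters:
            shared = set(cluster.members) & group.species
            if all(cluster.members[sp] == group.members[sp] for sp in shared):
                cluster.members.update(group.members)
                cluster.seeds.add(group.seed)
                if group.gene_id < cluster.representative.gene_id:
                    cluster.representative = group
                placed = True
                break
        if not placed:
            clusters.append(
                _Cluster(
                    representative=group,
                    members=dict(group.members),
                    seeds={group.seed},
                )
            )

    all_seeds = set(per_seed)
    merged: list[OrthologGroup] = []
    for cluster in clusters:
        if mode == "intersection" and cluster.seeds != all_seeds:
            continue
        rep = cluster.representative
        merged.append(
            OrthologGroup(gene_id=rep.gene_id, seed=rep.seed, members=rep.members)
        )
    merged.sort(key=lambda g: g.gene_id)
    return merged


def write_group_table(
    groups: Sequence[OrthologGroup], path: str | Path | None = None
) -> str:
    """Ortholog groups as a TSV: gene_id, seed, species, member_id."""
    lines = ["gene_id\tseed\tspecies\tmember_id"]
    for group in sorted(groups, key=lambda g: g.gene_id):
        for species in sorted(group.members):
            lines.append(
                f"{group.gene_id}\t{group.seed}\t{species}\t{group.members[species]}"
            )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
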