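"""Hold-out validation of a selected marker gene set.

Two tests establish that markers selected on training species (T-set)
generalize to held-out species (V-set):

* **one-species-at-a-time** - for each held-out species, the reference
  tree over the training species plus that species (built from all
  widespread genes) is compared with the tree built from the marker genes
  only; the species is correctly placed when the bipartitions whose
  smaller side contains it coincide in both trees.
* **cross-validation** - the reference topology derived from all
  single-copy genes of the V-set alone is compared with the marker-gene
  concatenation tree over the same species.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .phylo_io import GAP, Alignment, Tree, concatenate_alignments, write_newick
from .tree_build import NeighborJoiningBuilder
from .tree_compare import TreeComparisonError, bipartition_set, rf_distance
from .marker_selection import Builder, _as_dict

__all__ = [
    "ValidationConfig",
    "SpeciesValidation",
    "CrossValidation",
    "ValidationReport",
    "one_species_at_a_time",
    "cross_validate",
]


@dataclass(frozen=True)
class ValidationConfig:
    require_placement: bool = True
    max_wrong_split_fraction: float | None = None  # None: placement only
    cross_nrf_threshold: float = 0.0


@dataclass(frozen=True)
class SpeciesValidation:
    species: str
    markers_found: int
    markers_total: int
    testable: bool
    placement_correct: bool | None
    wrong_split_fraction: float | None


@dataclass(frozen=True)
class CrossValidation:
    reference_tree: Tree
    marker_tree: Tree
    rf: int
    normalized_rf: float


@dataclass(frozen=True)
class ValidationReport:
    per_species: Mapping[str, SpeciesValidation]
    cross: CrossValidation | None
    passed: bool

    def to_dict(self) -> dict:
        out: dict = {"passed": self.passed, "per_species": {}, "cross": None}
        for sp in sorted(self.per_species):
            rec = self.per_species[sp]
            out["per_species"][sp] = {
                "markers_found": rec.markers_found,
                "markers_total": rec.markers_total,
                "testable": rec.testable,
                "placement_correct": rec.placement_correct,
                "wrong_split_fraction": rec.wrong_split_fraction,
            }
        if self.cross is not None:
            out["cross"] = {
                "rf": self.cross.rf,
                "normalized_rf": self.cross.normalized_rf,
                "reference_tree": write_newick(self.cross.reference_tree),
                "marker_tree": write_newick(self.cross.marker_tree),
            }
        return out

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )


def _species_splits(tree: Tree, species: str) -> frozenset:
    """Bipartitions whose (canonical, smaller) side contains the species."""
    return frozenset(b for b in bipartition_set(tree) if species in b.side)


def _usable_homolog(value: object) -> str | None:
    """A homolog is usable when it is a single sequence; lists model
    multi-copy detections and None/missing model absence."""
    if isinstance(value, str):
        return value
    if isinstance(value, (list, tuple)) and len(value) == 1 and isinstance(value[0], str):
        return value[0]
    return None


def one_species_at_a_time(
    marker_set: Sequence[str],
    t_alignments: Mapping[str, Alignment] | Iterable[Alignment],
    v_homologs: Mapping[str, Mapping[str, object]],
    builder: Builder | None = None,
    cfg: ValidationConfig | None = None,
) -> ValidationReport:
    """Test A: place each held-out species into the training tree.

    ``t_alignments`` are all widespread genes over the training species;
    ``v_homologs`` maps held-out species -> gene id -> homolog sequence
    (aligned to the gene's columns; a list of several sequences marks a
    multi-copy detection, which drops the gene for that species). For each
    species the expanded reference (all genes, missing homologs gap-filled)
    is compared to the marker-genes-only tree over the same taxa.
    """
    cfg = cfg or ValidationConfig()
    builder = builder or NeighborJoiningBuilder()
    t_alignments = _as_dict(t_alignments)
    marker_set = sorted(dict.fromkeys(marker_set))
    missing_markers = [g for g in marker_set if g not in t_alignments]
    if missing_markers:
        raise TreeComparisonError(
            f"marker genes absent from training alignments: {missing_markers}"
        )
    t_species = sorted(
        set().union(*(aln.species for aln in t_alignments.values()))
    )
    per_species: dict[str, SpeciesValidation] = {}
    for species in sorted(v_homologs):
        homologs = v_homologs[species]
        usable = {
            g: seq
            for g in marker_set
            if (seq := _usable_homolog(homologs.get(g))) is not None
        }
        if not usable:
            per_species[species] = SpeciesValidation(
                species, 0, len(marker_set), False, None, None
            )
            continue
        taxa = t_species + [species]

        def expanded(gene_id: str) -> Alignment:
            aln = t_alignments[gene_id]
            seq = _usable_homolog(homologs.get(gene_id))
            if seq is None:
                seq = GAP * aln.length
            elif len(seq) != aln.length:
                raise TreeComparisonError(
                    f"homolog of {gene_id} for {species} has length {len(seq)}, "
                    f"expected {aln.length}"
                )
            rows = [
                (sp, aln.get(sp) if sp in aln else GAP * aln.length)
                for sp in t_species
            ]
            rows.append((species, seq))
            return Alignment(aln.gene_id, rows)

        all_genes = [expanded(g) for g in sorted(t_alignments)]
        marker_genes = [expanded(g) for g in usable]
        reference_tree = builder(concatenate_alignments(all_genes, species=taxa))
        marker_tree = builder(concatenate_alignments(marker_genes, species=taxa))
        _, wrong_fraction = rf_distance(reference_tree, marker_tree)
        placement = _species_splits(reference_tree, species) == _species_splits(
            marker_tree, species
        )
        per_species[species] = SpeciesValidation(
            species=species,
            markers_found=len(usable),
            markers_total=len(marker_set),
            testable=True,
            placement_correct=placement,
            wrong_split_fraction=wrong_fraction,
        )
    testable = [r for r in per_species.values() if r.testable]
    passed = bool(testable)
    for rec in testable:
        if cfg.require_placement and not rec.placement_correct:
            passed = False
        if (
            cfg.max_wrong_split_fraction is not None
            and rec.wrong_split_fraction > cfg.max_wrong_split_fraction
        ):
            passed = False
    return ValidationReport(per_species=per_species, cross=None, passed=passed)


def cross_validate(
    marker_set: Sequence[str],
    v_alignments: Mapping[str, Alignment] | Iterable[Alignment],
    builder: Builder | None = None,
    cfg: ValidationConfig | None = None,
) -> ValidationReport:
    """Test B: reference vs marker topology on the held-out species alone.

    The reference is built from the concatenation of *all* single-copy
    genes over the V-set; the marker tree from the marker genes only.
    Markers absent from the V-set gene collection are dropped with a
    warning. Passes when the normalized RF distance is at most the
    configured threshold (default 0).
    """
    cfg = cfg or ValidationConfig()
    builder = builder or NeighborJoiningBuilder()
    v_alignments = _as_dict(v_alignments)
    if not v_alignments:
        raise TreeComparisonError("no hold-out alignments supplied")
    v_species = sorted(
        set().union(*(aln.species for aln in v_alignments.values()))
    )
    if len(v_species) < 4:
        raise TreeComparisonError(
            f"only {len(v_species)} hold-out species; need >= 4 for any "
            "non-trivial split"
        )
    marker_set = sorted(dict.fromkeys(marker_set))
    present = [g for g in marker_set if g in v_alignments]
    absent = sorted(set(marker_set) - set(present))
    if absent:
        warnings.warn(
            f"marker genes absent from hold-out set dropped: {absent}",
            stacklevel=2,
        )
    if not present:
        raise TreeComparisonError("no marker gene present in the hold-out set")
    all_concat = concatenate_alignments(
        [v_alignments[g].restrict(v_species, fill_missing=True) for g in sorted(v_alignments)]
    )
    marker_concat = concatenate_alignments(
        [v_alignments[g].restrict(v_species, fill_missing=True) for g in present]
    )
    reference_tree = builder(all_concat)
    marker_tree = builder(marker_concat)
    rf, nrf = rf_distance(reference_tree, marker_tree)
    cross = CrossValidation(
        reference_tree=reference_tree,
        marker_tree=marker_tree,
        rf=rf,
        normalized_rf=nrf,
    )
    return ValidationReport(
        per_species={},
        cross=cross,
        passed=nrf <= cfg.cross_nrf_threshold,
    )
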