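"""Cross-lineage comparison of presence/absence calls.

Merges statuses computed for a focal species with statuses imported for
other species into one matrix, counts Venn-style sharing categories
(shared by all, shared with exactly one other lineage, unique to the focal
lineage), and compares protein-domain identifier sets between orthologues.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coverage import PavCall, LOST, CONSERVED, INDETERMINATE, NO_DATA

__all__ = [
    "PavMatrix",
    "VennCounts",
    "build_pav_matrix",
    "venn_categories",
    "compare_domain_sets",
    "IDENTICAL",
    "DIFFERENT",
    "NO_DOMAINS",
]

IDENTICAL = "IDENTICAL"
DIFFERENT = "DIFFERENT"
NO_DOMAINS = "NO_DOMAINS"

_OPPOSITE = {CONSERVED: LOST, LOST: CONSERVED}
_VALID = {LOST, CONSERVED, INDETERMINATE, NO_DATA}


@dataclass
class PavMatrix:
    """Rectangular group x species status table (LOST/CONSERVED/INDETERMINATE/NO_DATA)."""

    table: pd.DataFrame  # index: group ids, columns: species, values: status strings

    def __post_init__(self) -> None:
        bad = set(self.table.values.ravel()) - _VALID
        if bad:
            raise ValueError(f"unknown status labels in matrix: {sorted(bad)}")
        self.table.index.name = "group"

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    @property
    def groups(self) -> list[str]:
        return list(self.table.index)

    def status(self, group: str, species: str) -> str:
        return self.table.at[group, species]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="group")

    @classmethod
    def from_tsv(cls, path) -> "PavMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="group", dtype=str))


def build_pav_matrix(
    computed: list[PavCall],
    focal_species: str,
    imported: dict[tuple[str, str], str],
    species_order: list[str],
) -> PavMatrix:
    """Merge focal-species calls with an imported status table.

    ``imported`` maps (group, species) -> status, e.g. from
    :func:`pavcomp.io.read_status_tsv`. Cells never mentioned become
    NO_DATA. Conflicting duplicate statuses for a (group, species) cell
    raise (the focal species may not also appear in ``imported`` with a
    different status).
    """
    if focal_species not in species_order:
        raise ValueError(f"focal species {focal_species!r} not in species_order")
    cells: dict[tuple[str, str], str] = {}
    for call in computed:
        key = (call.group_id, focal_species)
        if key in cells and cells[key] != call.status:
            raise ValueError(f"conflicting computed statuses for {key}")
        cells[key] = call.status
    for (group, species), status in imported.items():
        if species not in species_order:
            continue
        key = (group, species)
        if key in cells and cells[key] != status:
            raise ValueError(
                f"conflicting statuses for {key}: {cells[key]} vs {status}"
            )
        cells[key] = status
    groups = sorted({g for g, _ in cells})
    data = {
        sp: [cells.get((g, sp), NO_DATA) for g in groups] for sp in species_order
    }
    return PavMatrix(pd.DataFrame(data, index=groups, columns=list(species_order)))


@dataclass(frozen=True)
class VennCounts:
    """Sharing categories for one status across a focal species and two others.

    Rows where a non-focal cell is NO_DATA or INDETERMINATE count toward
    ``focal_total`` but toward none of the three sharing categories, so
    shared_all + shared_with_exactly_one + focal_unique <= focal_total; the
    shortfall is reported as ``unclassified``.
    """

    focal_total: int
    shared_all: int
    shared_with_exactly_one: int
    focal_unique: int
    others_only: int

    @property
    def unclassified(self) -> int:
        return self.focal_total - (
            self.shared_all + self.shared_with_exactly_one + self.focal_unique
        )


def venn_categories(
    matrix: PavMatrix,
    focal: str,
    others: tuple[str, str],
    status_of_interest: str,
) -> VennCounts:
    """Count sharing categories for ``status_of_interest`` (LOST or CONSERVED).

    The "opposite definite status" of CONSERVED is LOST and vice versa:
    a row is focal_unique only when both other species hold the opposite
    definite status, and shared_with_exactly_one requires the non-sharing
    species to hold it too. others_only counts rows where both others hold
    the status but the focal species holds the opposite.
    """
    if status_of_interest not in _OPPOSITE:
        raise ValueError("status_of_interest must be LOST or CONSERVED")
    sp1, sp2 = others
    for sp in (focal, sp1, sp2):
        if sp not in matrix.species:
            raise ValueError(f"unknown species {sp!r}")
    if focal in others:
        raise ValueError("focal species cannot be one of the others")
    opposite = _OPPOSITE[status_of_interest]
    focal_total = shared_all = shared_one = unique = others_only = 0
    for group in matrix.groups:
        f = matrix.status(group, focal)
        a = matrix.status(group, sp1)
        b = matrix.status(group, sp2)
        if f == status_of_interest:
            focal_total += 1
            if a == status_of_interest and b == status_of_interest:
                shared_all += 1
            elif (a == status_of_interest and b == opposite) or (
                b == status_of_interest and a == opposite
            ):
                shared_one += 1
            elif a == opposite and b == opposite:
                unique += 1
            # NO_DATA / INDETERMINATE in a non-focal cell: focal_total only
        elif f == opposite and a == status_of_interest and b == status_of_interest:
            others_only += 1
    return VennCounts(focal_total, shared_all, shared_one, unique, others_only)


def compare_domain_sets(focal_domains: set[str], reference_domains: set[str]) -> str:
    """Compare protein-domain id sets between a focal gene and its reference orthologue.

    IDENTICAL: equal and non-empty; NO_DOMAINS: focal gene has none assigned;
    DIFFERENT: anything else (fewer, extra or different domains).
    """
    focal = set(focal_domains)
    if not focal:
        return NO_DOMAINS
    return IDENTICAL if focal == set(reference_domains) else DIFFERENT
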