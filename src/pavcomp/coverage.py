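"""Horizontal (breadth) coverage of reference CDSs and gene-loss calls.

For each reference CDS, horizontal coverage is the percentage of its length
covered by at least one mapped read (the union of hit subject intervals —
breadth, not depth). Per orthologue group, coverage is averaged within each
species over that species' member genes and then across species; the group
mean drives the presence/absence call:

    mean < lost_max (default 2%)        -> LOST
    mean > conserved_min (default 50%)  -> CONSERVED
    lost_max <= mean <= conserved_min   -> INDETERMINATE
    no species with data                -> NO_DATA

Thresholds are strict inequalities; exact-threshold ties land in
INDETERMINATE rather than being silently binned.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import OrthoGroupSet
from .io import CdsCatalog, HspRecord

__all__ = [
    "CoverageRecord",
    "GroupCoverage",
    "PavCall",
    "union_covered_bases",
    "horizontal_coverage",
    "group_mean_coverage",
    "classify",
    "classify_all",
    "write_coverage_tsv",
    "write_group_tsv",
]

LOST = "LOST"
CONSERVED = "CONSERVED"
INDETERMINATE = "INDETERMINATE"
NO_DATA = "NO_DATA"


@dataclass(frozen=True)
class CoverageRecord:
    species_id: str
    gene_id: str
    covered_bases: int
    cds_length: int
    horizontal_coverage: float  # percentage

    def __post_init__(self) -> None:
        if not 0 <= self.covered_bases <= self.cds_length:
            raise ValueError(
                f"{self.gene_id}: covered {self.covered_bases} outside "
                f"[0, {self.cds_length}]"
            )


@dataclass(frozen=True)
class GroupCoverage:
    group_id: str
    per_species_coverage: dict[str, float | None]  # None = NA (no member/length)
    mean_coverage: float | None  # arithmetic mean over non-NA species


@dataclass(frozen=True)
class PavCall:
    group_id: str
    status: str
    mean_coverage: float | None


def union_covered_bases(intervals, cds_length: int) -> int:
    """Number of bases covered by the union of 1-based inclusive intervals.

    Intervals are clipped to [1, cds_length]; order and duplication are
    irrelevant. An interval entirely outside the CDS contributes nothing.
    """
    if cds_length < 0:
        raise ValueError("negative CDS length")
    clipped = []
    for start, end in intervals:
        if end < start:
            raise ValueError(f"negative-length interval ({start}, {end})")
        s, e = max(start, 1), min(end, cds_length)
        if s <= e:
            clipped.append((s, e))
    clipped.sort()
    covered = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        elif e > cur_e:
            cur_e = e
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered


def horizontal_coverage(hits: list[HspRecord], catalog: CdsCatalog) -> list[CoverageRecord]:
    """One CoverageRecord per catalog CDS, including zero-coverage ones.

    Every hit subject id must resolve in the catalog; unknown subjects are
    reported together in one error.
    """
    by_subject: dict[str, list[tuple[int, int]]] = {}
    unknown = set()
    for h in hits:
        if catalog.species_of(h.subject_id) is None:
            unknown.add(h.subject_id)
        else:
            by_subject.setdefault(h.subject_id, []).append(h.subject_interval)
    if unknown:
        raise ValueError(
            f"hits reference subjects absent from the catalog: {sorted(unknown)}"
        )
    records = []
    for sp, gene, seq in catalog.items():
        length = len(seq)
        covered = union_covered_bases(by_subject.get(gene, ()), length)
        records.append(
            CoverageRecord(sp, gene, covered, length, 100.0 * covered / length)
        )
    return records


def group_mean_coverage(
    records: list[CoverageRecord],
    groups: OrthoGroupSet,
    absent_species_as_zero: bool = False,
) -> list[GroupCoverage]:
    """Average coverage per species (over member genes) then across species.

    A species without a member gene — or whose members have no coverage
    record — is NA and excluded from the group mean by default. With
    ``absent_species_as_zero`` such species count as 0 instead (treating
    reference incompleteness as absence).
    """
    by_gene = {(r.species_id, r.gene_id): r for r in records}
    out = []
    for gid, members in groups.items():
        if not any(members.values()):
            raise ValueError(f"group {gid!r} has no member genes")
        per_species: dict[str, float | None] = {}
        for sp, genes in members.items():
            vals = [
                by_gene[(sp, g)].horizontal_coverage
                for g in genes
                if (sp, g) in by_gene and by_gene[(sp, g)].cds_length > 0
            ]
            per_species[sp] = sum(vals) / len(vals) if vals else None
        if absent_species_as_zero:
            usable = [v if v is not None else 0.0 for v in per_species.values()]
        else:
            usable = [v for v in per_species.values() if v is not None]
        mean = sum(usable) / len(usable) if usable else None
        out.append(GroupCoverage(gid, per_species, mean))
    return out


def classify(
    group_cov: GroupCoverage,
    lost_max: float = 2.0,
    conserved_min: float = 50.0,
) -> PavCall:
    """Call a group LOST / CONSERVED / INDETERMINATE / NO_DATA from its mean coverage."""
    if not 0 <= lost_max < conserved_min <= 100:
        raise ValueError(
            f"thresholds must satisfy 0 <= lost_max < conserved_min <= 100, "
            f"got {lost_max}/{conserved_min}"
        )
    mean = group_cov.mean_coverage
    if mean is None:
        status = NO_DATA
    elif mean < lost_max:
        status = LOST
    elif mean > conserved_min:
        status = CONSERVED
    else:
        status = INDETERMINATE
    return PavCall(group_cov.group_id, status, mean)


def classify_all(
    group_covs: list[GroupCoverage],
    lost_max: float = 2.0,
    conserved_min: float = 50.0,
) -> list[PavCall]:
    return [classify(gc, lost_max, conserved_min) for gc in group_covs]


def write_coverage_tsv(path, records: list[CoverageRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("species\tgene\tcovered_bases\tcds_length\thorizontal_coverage\n")
        for r in sorted(records, key=lambda r: (r.species_id, r.gene_id)):
            fh.write(
                f"{r.species_id}\t{r.gene_id}\t{r.covered_bases}"
                f"\t{r.cds_length}\t{r.horizontal_coverage:.4f}\n"
            )


def write_group_tsv(path, group_covs: list[GroupCoverage], calls: list[PavCall]) -> None:
    status = {c.group_id: c.status for c in calls}
    species = sorted({sp for gc in group_covs for sp in gc.per_species_coverage})
    with open(path, "w") as fh:
        fh.write("group\t" + "\t".join(species) + "\tmean_coverage\tstatus\n")
        for gc in sorted(group_covs, key=lambda g: g.group_id):
            cells = [
                "NA" if gc.per_species_coverage.get(sp) is None
                else f"{gc.per_species_coverage[sp]:.4f}"
                for sp in species
            ]
            mean = "NA" if gc.mean_coverage is None else f"{gc.mean_coverage:.4f}"
            fh.write(f"{gc.group_id}\t" + "\t".join(cells) + f"\t{mean}\t{status[gc.group_id]}\n")
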