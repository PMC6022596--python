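"""End-to-end orchestration from a single YAML config.

Runs formats_io -> coverage -> comparative stages (plus optional
clustering, enrichment and convergence-scan stages) with deterministic
seeding, stage-tagged stderr logging, intermediate files always written for
auditability, and a machine-readable JSON run summary carrying per-stage
input/output checksums.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
from dataclasses import dataclass, field
from importlib.metadata import version, PackageNotFoundError

import yaml

from . import cluster as _cluster
from . import compare as _compare
from . import convergence as _convergence
from . import coverage as _coverage
from . import enrichment as _enrichment
from . import io as _io

__all__ = ["RunConfig", "load_config", "run_pav", "run_all", "validate_summary"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class RunConfig:
    """Paths, thresholds and species roles for one pipeline run."""

    out_dir: str
    # inputs (either precomputed hits or reads to map with the built-in mapper)
    reference_fasta: dict[str, str] = field(default_factory=dict)  # species -> path
    groups_tsv: str | None = None
    hits_tsv: str | None = None
    reads_fastq: list[str] = field(default_factory=list)
    imported_status_tsv: str | None = None
    # optional stage inputs
    protein_hits_tsv: str | None = None
    species_map_tsv: str | None = None
    obo: str | None = None
    annotation_tsv: str | None = None
    fg_genes: str | None = None
    bg_genes: str | None = None
    msa_fasta: str | None = None
    partition_tsv: str | None = None
    # species roles
    focal_species: str = "QUERY"
    species_order: list[str] = field(default_factory=list)
    target_species: list[str] = field(default_factory=list)
    outgroup_species: list[str] = field(default_factory=list)
    comparison_others: list[str] = field(default_factory=list)
    # thresholds
    evalue_max: float = 1e-5
    lost_max: float = 2.0
    conserved_min: float = 50.0
    inflation: float = 1.5
    bg_conservation_min: float = 1.0
    map_k: int = 21
    min_match_fraction: float = 0.9
    elim: bool = False
    seed: int = 0

    def input_paths(self) -> list[str]:
        paths = list(self.reference_fasta.values()) + list(self.reads_fastq)
        for p in (
            self.groups_tsv, self.hits_tsv, self.imported_status_tsv,
            self.protein_hits_tsv, self.species_map_tsv, self.obo,
            self.annotation_tsv, self.fg_genes, self.bg_genes,
            self.msa_fasta, self.partition_tsv,
        ):
            if p:
                paths.append(p)
        return paths

    def validate(self) -> None:
        missing = [p for p in self.input_paths() if not os.path.exists(p)]
        if missing:
            raise PipelineError(f"config: missing input file(s): {missing}")
        if not 0 <= self.lost_max < self.conserved_min <= 100:
            raise PipelineError(
                f"config: thresholds out of range: lost_max={self.lost_max}, "
                f"conserved_min={self.conserved_min}"
            )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise PipelineError(f"config {path}: {exc}") from None


def _log(stage: str, message: str) -> None:
    print(f"[pavcomp:{stage}] {message}", file=sys.stderr)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _pkg_version() -> str:
    try:
        return version("pavcomp")
    except PackageNotFoundError:
        return "unknown"


def run_pav(config: RunConfig) -> dict:
    """Map (or load) hits, compute coverage, classify, compare; return the summary."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {
        "version": _pkg_version(),
        "seed": config.seed,
        "stages": [],
        "inputs": {p: _sha256(p) for p in sorted(config.input_paths())},
        "outputs": {},
        "counts": {},
    }

    _log("io", "loading references and groups")
    try:
        catalog = _io.CdsCatalog.from_fasta(config.reference_fasta)
        groups = _cluster.OrthoGroupSet.from_tsv(config.groups_tsv)
    except Exception as exc:
        raise PipelineError(f"stage io: {exc}") from exc
    summary["stages"].append("io")

    if config.hits_tsv:
        _log("io", f"reading hits from {config.hits_tsv}")
        hits = _io.read_tabular_hits(config.hits_tsv, evalue_max=config.evalue_max)
    else:
        _log("map", f"mapping {len(config.reads_fastq)} read file(s) with the built-in mapper")
        reads = []
        for path in config.reads_fastq:
            reads.extend((rid, seq) for rid, seq, _q in _io.read_fastq(path))
        hits = _io.naive_map(
            reads, catalog, k=config.map_k, min_match_fraction=config.min_match_fraction
        )
        hits_path = os.path.join(config.out_dir, "hits.tsv")
        _io.write_tabular_hits(hits_path, hits)
        summary["outputs"]["hits"] = hits_path
        summary["counts"]["n_reads"] = len(reads)
        summary["counts"]["pct_reads_aligned"] = _io.aligned_read_fraction(
            len({h.query_id for h in hits}), len(reads)
        )
        summary["stages"].append("map")
    summary["counts"]["n_hits"] = len(hits)

    _log("coverage", "computing horizontal coverage and PAV calls")
    try:
        records = _coverage.horizontal_coverage(hits, catalog)
        group_covs = _coverage.group_mean_coverage(records, groups)
        calls = _coverage.classify_all(group_covs, config.lost_max, config.conserved_min)
    except Exception as exc:
        raise PipelineError(f"stage coverage: {exc}") from exc
    cov_path = os.path.join(config.out_dir, "coverage.tsv")
    grp_path = os.path.join(config.out_dir, "group_status.tsv")
    _coverage.write_coverage_tsv(cov_path, records)
    _coverage.write_group_tsv(grp_path, group_covs, calls)
    summary["outputs"]["coverage"] = cov_path
    summary["outputs"]["group_status"] = grp_path
    by_status: dict[str, int] = {}
    for c in calls:
        by_status[c.status] = by_status.get(c.status, 0) + 1
    summary["counts"]["status"] = by_status
    summary["stages"].append("coverage")

    if config.imported_status_tsv and len(config.comparison_others) == 2:
        _log("compare", "building PAV matrix and Venn categories")
        try:
            imported = _io.read_status_tsv(config.imported_status_tsv)
            order = config.species_order or (
                [config.focal_species] + list(config.comparison_others)
            )
            matrix = _compare.build_pav_matrix(calls, config.focal_species, imported, order)
            venn = {
                status: _compare.venn_categories(
                    matrix, config.focal_species,
                    tuple(config.comparison_others), status,
                ).__dict__
                for status in (_coverage.CONSERVED, _coverage.LOST)
            }
        except Exception as exc:
            raise PipelineError(f"stage compare: {exc}") from exc
        matrix_path = os.path.join(config.out_dir, "pav_matrix.tsv")
        matrix.to_tsv(matrix_path)
        summary["outputs"]["pav_matrix"] = matrix_path
        summary["counts"]["venn"] = venn
        summary["stages"].append("compare")

    summary["outputs"] = {
        name: {"path": p, "sha256": _sha256(p)} for name, p in summary["outputs"].items()
    }
    summary_path = os.path.join(config.out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _log("done", f"summary written to {summary_path}")
    return summary


def run_all(config: RunConfig) -> dict:
    """run_pav plus the clustering / enrichment / convergence stages when configured."""
    summary = run_pav(config)
    out = config.out_dir

    if config.protein_hits_tsv:
        _log("cluster", "Markov clustering of protein similarity graph")
        try:
            hits = _io.read_tabular_hits(config.protein_hits_tsv, config.evalue_max)
            smap = (
                _cluster.read_species_map(config.species_map_tsv)
                if config.species_map_tsv else None
            )
            graph = _cluster.build_graph(hits, config.evalue_max, species_map=smap)
            clusters = _cluster.mcl(graph, inflation=config.inflation)
        except Exception as exc:
            raise PipelineError(f"stage cluster: {exc}") from exc
        path = os.path.join(out, "clusters.tsv")
        clusters.to_tsv(path)
        summary["outputs"]["clusters"] = {"path": path, "sha256": _sha256(path)}
        summary["counts"]["n_clusters"] = len(clusters)
        if config.target_species:
            specific = _cluster.select_lineage_specific(
                clusters, set(config.target_species), set(config.outgroup_species)
            )
            spath = os.path.join(out, "lineage_specific.tsv")
            specific.to_tsv(spath)
            summary["outputs"]["lineage_specific"] = {
                "path": spath, "sha256": _sha256(spath)
            }
            summary["counts"]["n_lineage_specific"] = len(specific)
        summary["stages"].append("cluster")

    if config.obo and config.annotation_tsv and config.fg_genes and config.bg_genes:
        _log("enrich", "term enrichment")
        try:
            dag = _io.read_obo(config.obo)
            direct = _io.read_annotation_tsv(config.annotation_tsv)
            annotation = _enrichment.propagate_annotations(dag, direct)
            fg = set(open(config.fg_genes).read().split())
            bg = set(open(config.bg_genes).read().split())
            runner = _enrichment.elim_enrichment if config.elim else _enrichment.classic_enrichment
            results = runner(dag, annotation, fg, bg)
        except Exception as exc:
            raise PipelineError(f"stage enrich: {exc}") from exc
        path = os.path.join(out, "enrichment.tsv")
        with open(path, "w") as fh:
            fh.write("term\tname\tfg_annotated\tfg_total\tbg_annotated\tbg_total\tp_value\tbh_q\n")
            for r in results:
                fh.write(
                    f"{r.term_id}\t{r.name}\t{r.fg_annotated}\t{r.fg_total}"
                    f"\t{r.bg_annotated}\t{r.bg_total}\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
                )
        summary["outputs"]["enrichment"] = {"path": path, "sha256": _sha256(path)}
        summary["counts"]["n_terms_tested"] = len(results)
        summary["stages"].append("enrich")

    if config.msa_fasta and config.partition_tsv:
        _log("convscan", "scanning MSA for foreground-specific columns")
        try:
            fg_taxa, bg_taxa = set(), set()
            with open(config.partition_tsv) as fh:
                for line in fh:
                    line = line.strip()
                    if not line:
                        continue
                    taxon, role = line.split("\t")
                    if role == "foreground":
                        fg_taxa.add(taxon)
                    elif role == "background":
                        bg_taxa.add(taxon)
                    elif role != "ignore":
                        raise ValueError(f"unknown partition role {role!r}")
            msa = _io.read_msa_fasta(config.msa_fasta, fg_taxa, bg_taxa)
            sites = _convergence.scan_columns(
                msa, bg_conservation_min=config.bg_conservation_min
            )
            report = _convergence.column_report(sites, msa)
        except Exception as exc:
            raise PipelineError(f"stage convscan: {exc}") from exc
        path = os.path.join(out, "convergent_sites.tsv")
        report.to_csv(path, sep="\t", index=False)
        summary["outputs"]["convergent_sites"] = {"path": path, "sha256": _sha256(path)}
        summary["counts"]["n_convergent_sites"] = len(sites)
        summary["stages"].append("convscan")

    summary_path = os.path.join(out, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


SUMMARY_REQUIRED_KEYS = {"version", "seed", "stages", "inputs", "outputs", "counts"}


def validate_summary(summary: dict) -> None:
    """Check the run-summary JSON against its schema; raises on violation."""
    missing = SUMMARY_REQUIRED_KEYS - set(summary)
    if missing:
        raise ValueError(f"summary missing keys: {sorted(missing)}")
    if not isinstance(summary["stages"], list) or not summary["stages"]:
        raise ValueError("summary.stages must be a non-empty list")
    for name, entry in summary["outputs"].items():
        if not {"path", "sha256"} <= set(entry):
            raise ValueError(f"summary.outputs[{name!r}] lacks path/sha256")
    if not isinstance(summary["counts"], dict):
        raise ValueError("summary.counts must be a mapping")
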