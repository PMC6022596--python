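"""Seed-reproducible synthetic inputs with recorded ground truth.

Emulates the data a gene presence/absence study consumes: a panel of
reference species whose CDSs fall into single-copy orthologue groups, a
query genome with a planted subset of those orthologues deleted, uniform
paired-end shotgun reads with substitution errors, protein MSAs with planted
foreground-specific columns, and an annotated gene universe with planted
term enrichment. Every generator takes an explicit seed and the same seed
reproduces byte-identical outputs.

Mutation model: i.i.d. per-site substitution at the stated rate to a
uniformly chosen different symbol; no indels. This keeps divergence
interpretable (the expected pairwise mismatch between two sequences mutated
independently from one ancestor at rate d is 1 - [(1-d)^2 + d^2/3] for a
4-letter alphabet) and the coverage ground truth exact.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .cluster import OrthoGroupSet
from .enrichment import GeneAnnotation, GoDag, propagate_annotations
from .io import CdsCatalog, Msa, reverse_complement, write_fasta, write_fastq

__all__ = [
    "SimTruth",
    "build_reference_panel",
    "plant_query_genome",
    "simulate_reads",
    "plant_msa",
    "plant_annotation",
    "write_simulation",
]

DNA = "ACGT"
AA = "ACDEFGHIKLMNPQRSTVWY"

PRESENT = "PRESENT"
LOST = "LOST"


@dataclass
class SimTruth:
    """Ground truth recorded by the generators."""

    group_status: dict[str, str] = field(default_factory=dict)  # group -> PRESENT/LOST
    query_divergence: float = 0.0
    read_error_rate: float = 0.0
    seed: int = 0
    planted_columns: list[int] = field(default_factory=list)  # 1-based MSA columns
    enriched_terms: dict[str, float] = field(default_factory=dict)  # term -> odds

    @property
    def lost_groups(self) -> set[str]:
        return {g for g, s in self.group_status.items() if s == LOST}

    @property
    def present_groups(self) -> set[str]:
        return {g for g, s in self.group_status.items() if s == PRESENT}

    def write_status_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.group_status):
                fh.write(f"{g}\t{self.group_status[g]}\n")


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = DNA) -> str:
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return rng.choice(letters, size=length).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator, alphabet: str = DNA) -> str:
    """i.i.d. per-site substitution at ``rate`` to a uniform different symbol."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
        # shift by 1..len-1 positions within the alphabet: always a different symbol
        pos = np.searchsorted(letters, arr[hit])
        shift = rng.integers(1, len(alphabet), size=hit.size)
        arr[hit] = letters[(pos + shift) % len(alphabet)]
    return arr.tobytes().decode()


def build_reference_panel(
    n_species: int,
    n_groups: int,
    gene_length_range: tuple[int, int],
    interspecies_divergence: float = 0.05,
    seed: int = 0,
) -> tuple[CdsCatalog, OrthoGroupSet]:
    """Reference CDS sets for a species panel sharing single-copy orthologues.

    Each group's member sequences are independent mutated copies of one
    random ancestral sequence, mutated at ``interspecies_divergence``; every
    group has exactly one member per species.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_groups < 1:
        raise ValueError("need at least 1 group")
    lo, hi = gene_length_range
    if not 0 < lo <= hi:
        raise ValueError(f"bad gene length range {gene_length_range}")
    if not 0 <= interspecies_divergence <= 0.5:
        raise ValueError("interspecies divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    species = [f"SP{i + 1:02d}" for i in range(n_species)]
    catalog = CdsCatalog()
    groups: dict[str, dict[str, list[str]]] = {}
    for g in range(1, n_groups + 1):
        gid = f"OG{g:05d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq(rng, length)
        members: dict[str, list[str]] = {}
        for sp in species:
            gene_id = f"{sp}_G{g:05d}"
            catalog.add(sp, gene_id, _mutate(ancestor, interspecies_divergence, rng))
            members[sp] = [gene_id]
        groups[gid] = members
    return catalog, OrthoGroupSet(groups)


def plant_query_genome(
    catalog: CdsCatalog,
    groups: OrthoGroupSet,
    loss_fraction: float,
    query_divergence: float = 0.02,
    intergenic_length: int = 200,
    seed: int = 0,
) -> tuple[str, SimTruth]:
    """Query genome retaining a diverged copy of each non-lost orthologue.

    Exactly round(loss_fraction * n_groups) groups are deleted outright (no
    homologous sequence anywhere in the genome). Each retained group appears
    once, as the first panel species' member mutated at ``query_divergence``,
    with i.i.d. uniform intergenic spacers (length uniform in
    [0.5x, 1.5x] of ``intergenic_length``) between and around genes.
    """
    if len(catalog) == 0 or len(groups) == 0:
        raise ValueError("empty catalog or group set")
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    gids = list(groups)  # sorted
    n_lost = round(loss_fraction * len(gids))
    lost = set(rng.choice(len(gids), size=n_lost, replace=False).tolist())
    truth = SimTruth(
        group_status={
            gid: (LOST if i in lost else PRESENT) for i, gid in enumerate(gids)
        },
        query_divergence=query_divergence,
        seed=seed,
    )

    def spacer() -> str:
        length = int(rng.integers(intergenic_length // 2, intergenic_length * 3 // 2 + 1))
        return _random_seq(rng, length)

    parts = [spacer()]
    for i, gid in enumerate(gids):
        if i in lost:
            continue
        members = groups.members(gid)
        first_sp = sorted(members)[0]
        template = catalog.genes(first_sp)[members[first_sp][0]]
        parts.append(_mutate(template, query_divergence, rng))
        parts.append(spacer())
    return "".join(parts), truth


def simulate_reads(
    genome: str,
    depth: float,
    read_length: int = 150,
    insert_mean: int = 400,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[tuple[str, str, str], tuple[str, str, str]]]:
    """Uniform paired-end shotgun reads with substitution errors.

    Returns ceil(depth * genome_length / (2 * read_length)) pairs of
    (id, sequence, quality) triples. Fragment starts are uniform over the
    valid positions, the insert size is constant at ``insert_mean``, mate 2
    is the reverse complement of the fragment's far end, and every base
    carries a constant placeholder quality (the pipeline never reads
    qualities).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not read_length <= insert_mean <= len(genome):
        raise ValueError(
            f"need read_length <= insert_mean <= genome length, got "
            f"{read_length}/{insert_mean}/{len(genome)}"
        )
    rng = np.random.default_rng(seed)
    n_pairs = math.ceil(depth * len(genome) / (2 * read_length))
    starts = rng.integers(0, len(genome) - insert_mean + 1, size=n_pairs)
    qual = "I" * read_length
    pairs = []
    for i, s in enumerate(starts, start=1):
        s = int(s)
        fwd = genome[s : s + read_length]
        rev = reverse_complement(genome[s + insert_mean - read_length : s + insert_mean])
        fwd = _mutate(fwd, error_rate, rng)
        rev = _mutate(rev, error_rate, rng)
        pairs.append(((f"read{i:07d}/1", fwd, qual), (f"read{i:07d}/2", rev, qual)))
    return pairs


def plant_msa(
    n_background: int,
    n_foreground: int,
    length: int,
    n_convergent: int,
    background_noise: float = 0.0,
    seed: int = 0,
) -> tuple[Msa, SimTruth]:
    """Protein MSA with planted foreground-specific columns.

    Planted columns carry one residue shared by every background taxon and a
    different residue shared by every foreground taxon. Non-planted columns
    are fully conserved across all taxa; with probability
    ``background_noise`` one taxon in such a column is mutated, chosen so
    the column still violates at least one call condition at any threshold
    (a background taxon when the background has >= 2 members, else a
    foreground taxon when the foreground has >= 2).
    """
    if n_foreground < 1:
        raise ValueError("need at least one foreground taxon")
    if n_background < 1:
        raise ValueError("need at least one background taxon")
    if n_convergent > length:
        raise ValueError("more planted columns than alignment columns")
    rng = np.random.default_rng(seed)
    fg = [f"fg{i + 1:02d}" for i in range(n_foreground)]
    bg = [f"bg{i + 1:02d}" for i in range(n_background)]
    planted = sorted(rng.choice(length, size=n_convergent, replace=False).tolist())
    planted_set = set(planted)
    cols: dict[str, list[str]] = {t: [] for t in fg + bg}
    aa = list(AA)
    for c in range(length):
        if c in planted_set:
            bg_res, fg_res = rng.choice(len(aa), size=2, replace=False)
            for t in bg:
                cols[t].append(aa[bg_res])
            for t in fg:
                cols[t].append(aa[fg_res])
        else:
            res = aa[int(rng.integers(len(aa)))]
            for t in fg + bg:
                cols[t].append(res)
            if background_noise > 0 and rng.random() < background_noise:
                if n_background >= 2:
                    victim = bg[int(rng.integers(n_background))]
                elif n_foreground >= 2:
                    victim = fg[int(rng.integers(n_foreground))]
                else:
                    victim = None
                if victim is not None:
                    alt = aa[(aa.index(res) + 1 + int(rng.integers(len(aa) - 1))) % len(aa)]
                    cols[victim][c] = alt
    msa = Msa(
        {t: "".join(s) for t, s in cols.items()},
        foreground=frozenset(fg),
        background=frozenset(bg),
    )
    truth = SimTruth(planted_columns=[c + 1 for c in planted], seed=seed)
    return msa, truth


def plant_annotation(
    n_genes: int,
    n_terms: int,
    dag_depth: int,
    foreground: set[str] | int,
    enriched_terms: int = 0,
    effect_odds: float = 1.0,
    seed: int = 0,
) -> tuple[GoDag, GeneAnnotation, SimTruth]:
    """Single-root acyclic term DAG plus gene annotations with planted enrichment.

    Terms are arranged in ``dag_depth`` levels below one root; each term has
    1-2 parents in the level above. Genes are annotated directly to leaf
    terms only; interior terms acquire genes through true-path propagation.
    Each leaf's background annotation probability is uniform in
    [0.05, 0.15]; for planted terms the foreground annotation odds are
    ``effect_odds`` times the background odds. ``effect_odds == 1`` plants
    nothing. ``foreground`` is either an explicit gene id set or a count of
    genes to mark as foreground.
    """
    if dag_depth < 1:
        raise ValueError("dag_depth must be >= 1 (a cyclic structure is impossible here)")
    if effect_odds < 1:
        raise ValueError("effect_odds must be >= 1")
    if n_terms < dag_depth + 1:
        raise ValueError("need at least one term per level plus the root")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    if isinstance(foreground, int):
        fg = set(rng.choice(genes, size=foreground, replace=False).tolist())
    else:
        fg = set(foreground)
        if not fg <= set(genes):
            raise ValueError("foreground names genes outside the universe")

    # DAG: root at level 0, remaining terms spread over dag_depth levels
    term_ids = [f"T{i + 1:07d}" for i in range(n_terms)]
    root = term_ids[0]
    rest = term_ids[1:]
    per_level = [[] for _ in range(dag_depth)]
    for i, t in enumerate(rest):
        per_level[i % dag_depth].append(t)
    terms = {t: {"name": f"term {t}", "namespace": "biological_process"} for t in term_ids}
    parents: dict[str, tuple[str, ...]] = {root: ()}
    for lvl, level_terms in enumerate(per_level):
        pool = [root] if lvl == 0 else per_level[lvl - 1]
        for t in level_terms:
            n_par = 1 if len(pool) == 1 else int(rng.integers(1, 3))
            chosen = rng.choice(len(pool), size=min(n_par, len(pool)), replace=False)
            parents[t] = tuple(sorted(pool[i] for i in chosen))
    dag = GoDag(terms=terms, parents=parents)

    leaves = per_level[-1]
    if enriched_terms > len(leaves):
        raise ValueError("more enriched terms requested than leaf terms available")
    if effect_odds == 1.0:
        enriched: list[str] = []
    else:
        pick = rng.choice(len(leaves), size=enriched_terms, replace=False)
        enriched = sorted(leaves[i] for i in pick)

    direct: dict[str, set[str]] = {g: set() for g in genes}
    for leaf in leaves:
        p_bg = float(rng.uniform(0.05, 0.15))
        odds_bg = p_bg / (1 - p_bg)
        if leaf in enriched:
            odds_fg = odds_bg * effect_odds
            p_fg = odds_fg / (1 + odds_fg)
        else:
            p_fg = p_bg
        draws = rng.random(n_genes)
        for g, u in zip(genes, draws):
            if u < (p_fg if g in fg else p_bg):
                direct[g].add(leaf)
    annotation = propagate_annotations(dag, direct)
    truth = SimTruth(seed=seed, enriched_terms={t: effect_odds for t in enriched})
    return dag, annotation, truth


def write_simulation(
    outdir,
    n_species: int = 5,
    n_groups: int = 300,
    gene_length_range: tuple[int, int] = (300, 1500),
    interspecies_divergence: float = 0.05,
    loss_fraction: float = 0.2,
    query_divergence: float = 0.02,
    intergenic_length: int = 200,
    depth: float = 10.0,
    read_length: int = 150,
    insert_mean: int = 400,
    error_rate: float = 0.01,
    seed: int = 0,
) -> dict[str, str]:
    """Generate and write a full simulated study to ``outdir``; returns file paths."""
    os.makedirs(outdir, exist_ok=True)
    catalog, groups = build_reference_panel(
        n_species, n_groups, gene_length_range, interspecies_divergence, seed
    )
    genome, truth = plant_query_genome(
        catalog, groups, loss_fraction, query_divergence, intergenic_length, seed + 1
    )
    pairs = simulate_reads(genome, depth, read_length, insert_mean, error_rate, seed + 2)
    paths = {}
    paths.update(catalog.write_fasta(outdir))
    paths["groups"] = os.path.join(outdir, "groups.tsv")
    groups.to_tsv(paths["groups"])
    paths["genome"] = os.path.join(outdir, "query_genome.fasta")
    write_fasta(paths["genome"], [("query_genome", genome)])
    paths["reads_1"] = os.path.join(outdir, "reads_1.fastq")
    paths["reads_2"] = os.path.join(outdir, "reads_2.fastq")
    write_fastq(paths["reads_1"], [p[0] for p in pairs])
    write_fastq(paths["reads_2"], [p[1] for p in pairs])
    paths["truth"] = os.path.join(outdir, "truth_status.tsv")
    truth.write_status_tsv(paths["truth"])
    return paths
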