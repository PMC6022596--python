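"""Readers and writers for the pipeline's external formats.

Covers FASTA/FASTQ, 12-column tabular alignment hits (qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore), a minimal
OBO 1.2 subset, annotation / orthologue-group / status TSVs and aligned-FASTA
MSAs, plus a naive exact-k-mer read mapper used as a self-contained stand-in
for an external seeded aligner.

Coordinates are 1-based inclusive throughout, following the tabular alignment
convention; subject intervals are strand-normalized at parse time
(s_start <= s_end) with the original orientation kept on a strand flag.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import obonet
from Bio import SeqIO

from .enrichment import GoDag, OntologyError

__all__ = [
    "HspRecord",
    "CdsCatalog",
    "Msa",
    "FormatError",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_obo",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_msa_fasta",
    "read_status_tsv",
    "write_status_tsv",
    "aligned_read_fraction",
    "naive_map",
    "reverse_complement",
]

STATUS_LABELS = frozenset({"LOST", "CONSERVED", "INDETERMINATE", "NO_DATA", "NA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file; message names the file/line where known."""


@dataclass(frozen=True)
class HspRecord:
    """One local alignment hit between a query (read or protein) and a subject.

    Subject coordinates are normalized so ``s_start <= s_end``; ``strand``
    records the original orientation ('+' if the hit was reported forward,
    '-' if the raw line had s_start > s_end).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"q_start {self.q_start} > q_end {self.q_end}")
        if self.s_start > self.s_end:
            raise ValueError("subject coordinates must be normalized (s_start <= s_end)")
        if min(self.q_start, self.s_start) < 1:
            raise ValueError("coordinates are 1-based; got a value < 1")
        if self.evalue < 0:
            raise ValueError("negative e-value")

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)


def read_tabular_hits(path, evalue_max: float = 1e-5) -> list[HspRecord]:
    """Parse 12-column tabular alignment hits, filtering on e-value.

    Hits with evalue > ``evalue_max`` are dropped at parse time (the
    pipeline's per-hit significance filter). Input order is preserved;
    reversed subject coordinates are normalized with strand='-'.
    """
    hits: list[HspRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                length, mism, gaps = int(cols[3]), int(cols[4]), int(cols[5])
                qs, qe, ss, se = (int(c) for c in cols[6:10])
                evalue, bits = float(cols[10]), float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if evalue > evalue_max:
                continue
            strand = "+"
            if ss > se:
                ss, se = se, ss
                strand = "-"
            hits.append(
                HspRecord(cols[0], cols[1], pident, length, mism, gaps,
                          qs, qe, ss, se, evalue, bits, strand)
            )
    return hits


def write_tabular_hits(path, hits: list[HspRecord]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            ss, se = (h.s_end, h.s_start) if h.strand == "-" else (h.s_start, h.s_end)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_length}"
                f"\t{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}"
                f"\t{ss}\t{se}\t{h.evalue:.3g}\t{h.bit_score:.1f}\n"
            )


class CdsCatalog:
    """Per-species coding-sequence sets: species -> gene -> sequence.

    Gene ids must be unique within a species; cross-species gene lookup
    additionally requires global uniqueness (enforced lazily on first use).
    """

    def __init__(self) -> None:
        self._species: dict[str, dict[str, str]] = {}
        self._gene_index: dict[str, str] | None = None

    @property
    def species(self) -> list[str]:
        return sorted(self._species)

    def add(self, species: str, gene_id: str, seq: str) -> None:
        genes = self._species.setdefault(species, {})
        if gene_id in genes:
            raise FormatError(f"duplicate gene id {gene_id!r} in species {species!r}")
        if not seq:
            raise FormatError(f"empty sequence for gene {gene_id!r}")
        genes[gene_id] = seq
        self._gene_index = None

    def genes(self, species: str) -> dict[str, str]:
        return self._species[species]

    def __len__(self) -> int:
        return sum(len(g) for g in self._species.values())

    def length(self, species: str, gene_id: str) -> int:
        return len(self._species[species][gene_id])

    def _index(self) -> dict[str, str]:
        if self._gene_index is None:
            idx: dict[str, str] = {}
            for sp, genes in self._species.items():
                for g in genes:
                    if g in idx:
                        raise FormatError(
                            f"gene id {g!r} occurs in species {idx[g]!r} and {sp!r}; "
                            "cross-species lookup needs globally unique ids"
                        )
                    idx[g] = sp
            self._gene_index = idx
        return self._gene_index

    def species_of(self, gene_id: str) -> str | None:
        return self._index().get(gene_id)

    def sequence(self, gene_id: str) -> str:
        sp = self.species_of(gene_id)
        if sp is None:
            raise KeyError(gene_id)
        return self._species[sp][gene_id]

    def items(self):
        for sp in self.species:
            for gene, seq in self._species[sp].items():
                yield sp, gene, seq

    @classmethod
    def from_fasta(cls, paths: dict[str, str | os.PathLike]) -> "CdsCatalog":
        cat = cls()
        for sp, path in paths.items():
            for gene, seq in read_fasta(path).items():
                cat.add(sp, gene, seq)
        return cat

    def write_fasta(self, directory, suffix: str = ".cds.fasta") -> dict[str, str]:
        paths = {}
        os.makedirs(directory, exist_ok=True)
        for sp in self.species:
            path = os.path.join(directory, f"{sp}{suffix}")
            write_fasta(path, self._species[sp].items())
            paths[sp] = path
        return paths


@dataclass
class Msa:
    """Aligned amino-acid sequences with a foreground/background partition."""

    sequences: dict[str, str]
    foreground: frozenset[str] = field(default_factory=frozenset)
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FormatError(f"ragged MSA: row lengths {sorted(lengths)}")
        self.foreground = frozenset(self.foreground)
        self.background = frozenset(self.background)
        if self.foreground & self.background:
            raise ValueError("foreground and background taxa overlap")
        unknown = (self.foreground | self.background) - set(self.sequences)
        if unknown:
            raise ValueError(f"partition names unknown taxa: {sorted(unknown)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, col: int) -> dict[str, str]:
        """Residues at 1-based alignment column ``col``."""
        return {t: s[col - 1] for t, s in self.sequences.items()}

    def with_partition(self, foreground, background) -> "Msa":
        return Msa(self.sequences, frozenset(foreground), frozenset(background))


def read_fasta(path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(path, records, width: int = 70) -> None:
    """Write (id, seq) pairs; accepts any iterable or a mapping."""
    if hasattr(records, "items"):
        records = records.items()
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(path, records) -> None:
    """Write (id, seq, qual) triples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_obo(path) -> GoDag:
    """Read an OBO 1.2 ontology into a GoDag (is_a edges only).

    Raises :class:`pavcomp.enrichment.OntologyError` on cycles or on a term
    whose is_a target is not itself declared.
    """
    graph = obonet.read_obo(str(path))
    terms: dict[str, dict] = {}
    parents: dict[str, tuple[str, ...]] = {}
    # nodes with no attributes were auto-created as targets of dangling edges,
    # not declared in a [Term] stanza
    for node, data in graph.nodes(data=True):
        if not data:
            continue
        terms[node] = {
            "name": data.get("name", node),
            "namespace": data.get("namespace", ""),
        }
    for node, data in graph.nodes(data=True):
        if not data:
            continue
        pars = tuple(data.get("is_a", ()))
        for p in pars:
            if p not in terms:
                raise OntologyError(
                    f"{path}: term {node!r} has undeclared is_a target {p!r}"
                )
        parents[node] = pars
    return GoDag(terms=terms, parents=parents)


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """gene TAB semicolon-joined term ids -> {gene: {terms}}."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'gene<TAB>terms', got {len(cols)} columns"
                )
            gene, terms = cols
            if gene in out:
                raise FormatError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            out[gene] = {t for t in terms.split(";") if t}
    return out


def write_annotation_tsv(path, annotation: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotation):
            fh.write(f"{gene}\t{';'.join(sorted(annotation[gene]))}\n")


def read_msa_fasta(path, foreground=(), background=()) -> Msa:
    seqs = read_fasta(path)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise FormatError(f"{path}: alignment rows have unequal lengths {sorted(lengths)}")
    return Msa(seqs, frozenset(foreground), frozenset(background))


def read_status_tsv(path) -> dict[tuple[str, str], str]:
    """group_id TAB species TAB status; status in the PAV vocabulary or NA."""
    out: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'group<TAB>species<TAB>status'"
                )
            group, species, status = cols
            if status not in STATUS_LABELS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown status label {status!r}"
                )
            key = (group, species)
            if key in out and out[key] != status:
                raise FormatError(
                    f"{path}: line {lineno}: conflicting duplicate status for {key}"
                )
            out[key] = "NO_DATA" if status == "NA" else status
    return out


def write_status_tsv(path, statuses: dict[tuple[str, str], str]) -> None:
    with open(path, "w") as fh:
        for (group, species) in sorted(statuses):
            fh.write(f"{group}\t{species}\t{statuses[(group, species)]}\n")


def aligned_read_fraction(n_aligned_reads: int, n_total_reads: int) -> float:
    """Percentage of reads with at least one alignment, round-half-up to 1 dp.

    A read counts once no matter how many hits it has; the two mates of a
    pair are independent reads.
    """
    if n_total_reads <= 0:
        raise ValueError("total read count must be positive")
    if not 0 <= n_aligned_reads <= n_total_reads:
        raise ValueError("aligned count outside [0, total]")
    pct = Decimal(100 * n_aligned_reads) / Decimal(n_total_reads)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# naive exact-k-mer read mapper


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def naive_map(
    reads,
    catalog: CdsCatalog,
    k: int = 21,
    min_match_fraction: float = 0.9,
) -> list[HspRecord]:
    """Map reads onto catalog CDSs by exact k-mer seeding + ungapped check.

    For each read and each strand, every shared exact k-mer proposes a
    gapless full-length placement (a diagonal); placements where the read
    lies entirely within the subject and the matched fraction over the whole
    read is >= ``min_match_fraction`` are reported once. A read placed
    verbatim inside a CDS is therefore always reported whenever
    ``k <= read length``. Reported e-values are a synthetic 0.0; the bit
    score is twice the match count.

    ``reads`` is an iterable of (read_id, sequence).
    """
    if len(catalog) == 0:
        raise ValueError("empty CDS catalog")
    subjects: list[tuple[str, np.ndarray]] = []
    index: dict[str, list[tuple[int, int]]] = {}
    for _sp, gene, seq in catalog.items():
        si = len(subjects)
        subjects.append((gene, _seq_array(seq)))
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((si, pos))

    hits: list[HspRecord] = []
    for read_id, seq in reads:
        if k > len(seq):
            raise ValueError(f"k={k} exceeds read length {len(seq)}")
        L = len(seq)
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            candidates: set[tuple[int, int]] = set()
            for off in range(L - k + 1):
                for si, pos in index.get(s[off : off + k], ()):
                    candidates.add((si, pos - off))
            sarr_read = _seq_array(s)
            for si, diag in sorted(candidates):
                gene, subj = subjects[si]
                if diag < 0 or diag + L > subj.size:
                    continue
                matches = int((subj[diag : diag + L] == sarr_read).sum())
                if matches / L >= min_match_fraction:
                    hits.append(
                        HspRecord(
                            query_id=read_id,
                            subject_id=gene,
                            pct_identity=round(100.0 * matches / L, 2),
                            aln_length=L,
                            mismatches=L - matches,
                            gap_opens=0,
                            q_start=1,
                            q_end=L,
                            s_start=diag + 1,
                            s_end=diag + L,
                            evalue=0.0,
                            bit_score=float(2 * matches),
                            strand=strand,
                        )
                    )
    return hits
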