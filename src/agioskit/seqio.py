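"""FASTA and tabular I/O: sequence records, paired gene sets, assemblies,
homology-hit tables and comparison matrices.

All coordinates are 1-based inclusive with explicit strand (GenBank
convention). FASTA headers are split on whitespace: the first token is the
record ID, the remainder the description.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

_ALPHABETS = {"nucleotide": NUCLEOTIDE_ALPHABET, "protein": PROTEIN_ALPHABET}


class SeqIOError(ValueError):
    """Raised for malformed sequence or table inputs."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence with a declared alphabet."""

    id: str
    residues: str
    alphabet: str  # "nucleotide" | "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIOError(f"invalid sequence ID: {self.id!r}")
        if self.alphabet not in _ALPHABETS:
            raise SeqIOError(f"unknown alphabet: {self.alphabet!r}")
        if len(self.residues) < 1:
            raise SeqIOError(f"empty sequence for record {self.id!r}")
        allowed = _ALPHABETS[self.alphabet]
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise SeqIOError(
                    f"record {self.id!r}: residue {ch!r} at position "
                    f"{pos + 1} not in {self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneCoords:
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise SeqIOError(
                f"bad coordinates on {self.contig_id}: {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Gene:
    gene_id: str
    cds: SequenceRecord
    protein: SequenceRecord
    coords: Optional[GeneCoords] = None


@dataclass
class GeneSet:
    """One genome's genes with paired nucleotide (CDS) and protein sequences."""

    genome_id: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise SeqIOError(
                    f"duplicate gene ID {g.gene_id!r} in gene set "
                    f"{self.genome_id!r}"
                )
            seen.add(g.gene_id)
            if len(g.cds) < 3:
                raise SeqIOError(
                    f"gene {g.gene_id!r}: CDS shorter than one codon"
                )
            _check_cds_protein_consistency(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def get(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _check_cds_protein_consistency(gene: Gene) -> None:
    """Warn (never raise) when a CDS does not translate to its protein.

    Real annotations contain pseudogenes and frameshifts; downstream code
    only needs the paired sequences, so a mismatch is flagged, not fatal.
    """
    n = len(gene.cds)
    if n % 3 != 0:
        logger.warning(
            "gene %s: CDS length %d not a multiple of 3", gene.gene_id, n
        )
        return
    try:
        from Bio.Seq import Seq

        aa = str(Seq(gene.cds.residues).translate())
    except Exception:  # ambiguous codons etc. — skip the check
        return
    prot = gene.protein.residues
    if aa == prot or (aa.endswith("*") and aa[:-1] == prot):
        return
    logger.warning(
        "gene %s: protein does not match CDS translation", gene.gene_id
    )


@dataclass
class Assembly:
    """A genome assembly as an ordered list of contigs."""

    genome_id: str
    contigs: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise SeqIOError(f"assembly {self.genome_id!r} has no contigs")
        for c in self.contigs:
            if c.alphabet != "nucleotide":
                raise SeqIOError(f"contig {c.id!r} is not nucleotide")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig_lengths(self) -> dict[str, int]:
        return {c.id: len(c) for c in self.contigs}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    IDs are the first whitespace-delimited header token; residues are
    uppercased and whitespace-stripped. Raises on an empty file, duplicate
    IDs, or residues outside ``alphabet``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split(None, 1)
        if not parts:
            raise SeqIOError(f"{path}: empty FASTA header")
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if rid in seen:
            raise SeqIOError(f"{path}: duplicate sequence ID {rid!r}")
        seen.add(rid)
        residues = "".join(chunks).upper()
        try:
            records.append(
                SequenceRecord(id=rid, residues=residues, alphabet=alphabet,
                               description=desc)
            )
        except SeqIOError as exc:
            raise SeqIOError(f"{path}: {exc}") from exc

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise SeqIOError(f"{path}: sequence data before header")
                chunks.append(line.replace(" ", ""))
        flush()

    if not records:
        raise SeqIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as FASTA, wrapping residue lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            seq = rec.residues
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_assembly(path: str | Path, genome_id: Optional[str] = None) -> Assembly:
    contigs = read_fasta(path, "nucleotide")
    if genome_id is None:
        genome_id = Path(path).stem
    return Assembly(genome_id=genome_id, contigs=contigs)


def load_geneset(fna_path: str | Path, faa_path: str | Path,
                 genome_id: str) -> GeneSet:
    """Pair nucleotide CDS and protein FASTA files into a gene set.

    Genes are matched on exact ID; output order follows the ``.fna`` file.
    Genes present in only one file are dropped and counted in a log message.
    Zero matched IDs is an error.
    """
    cds = {r.id: r for r in read_fasta(fna_path, "nucleotide")}
    prot = {r.id: r for r in read_fasta(faa_path, "protein")}
    shared = set(cds) & set(prot)
    if not shared:
        raise SeqIOError(
            f"no gene IDs shared between {fna_path} and {faa_path}"
        )
    dropped = (len(cds) - len(shared)) + (len(prot) - len(shared))
    if dropped:
        logger.warning(
            "genome %s: dropped %d unpaired gene(s) (%d CDS-only, %d protein-only)",
            genome_id, dropped, len(cds) - len(shared), len(prot) - len(shared),
        )
    genes = [
        Gene(gene_id=rid, cds=cds[rid], protein=prot[rid])
        for rid in cds  # insertion order == fna file order
        if rid in shared
    ]
    return GeneSet(genome_id=genome_id, genes=genes)


def read_gene_coords(path: str | Path) -> dict[str, GeneCoords]:
    """Read a gene-coordinate TSV: gene_id, contig, start, end, strand."""
    coords: dict[str, GeneCoords] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise SeqIOError(
                    f"{path}:{lineno}: expected 5 tab-separated fields"
                )
            gid, contig, start, end, strand = fields
            if gid in coords:
                raise SeqIOError(f"{path}:{lineno}: duplicate gene {gid!r}")
            coords[gid] = GeneCoords(contig, int(start), int(end), strand)
    return coords


# ---------------------------------------------------------------------------
# Hit tables (12-column tab-separated, BLAST outfmt-6 style)
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "query", "subject", "identity_pct", "alignment_length", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "e_value", "bit_score",
)


def write_hits_tsv(hits: Iterable, path: str | Path) -> None:
    """Write HomologyHit records in the ubiquitous 12-column tabular format."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join([
                    h.query_id, h.subject_id,
                    f"{h.identity_pct:.2f}", str(h.alignment_length),
                    str(h.mismatches), str(h.gap_opens),
                    str(h.qstart), str(h.qend), str(h.sstart), str(h.send),
                    f"{h.e_value:.3g}", f"{h.bit_score:.1f}",
                ]) + "\n"
            )


def read_hits_tsv(path: str | Path,
                  query_lengths: Optional[Mapping[str, int]] = None,
                  subject_lengths: Optional[Mapping[str, int]] = None) -> list:
    """Read a 12-column hit table into HomologyHit records.

    Coverages are derived from the aligned spans when sequence lengths are
    supplied; otherwise they default to 1.0 (externally produced tables are
    typically used only for significance-based ORFan calling, which ignores
    coverage). Raw scores are back-computed from bit scores.
    """
    from .orthology import HomologyHit  # deferred: avoid import cycle

    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise SeqIOError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, "
                    f"got {len(f)}"
                )
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            qcov = scov = 1.0
            if query_lengths is not None and f[0] in query_lengths:
                qcov = (abs(qend - qstart) + 1) / query_lengths[f[0]]
            if subject_lengths is not None and f[1] in subject_lengths:
                scov = (abs(send - sstart) + 1) / subject_lengths[f[1]]
            e_value = float(f[10])
            if e_value <= 0.0:
                e_value = 1e-300  # tabular outputs print 0.0 for tiny E
            hits.append(HomologyHit(
                query_id=f[0], subject_id=f[1],
                identity_pct=float(f[2]), alignment_length=int(f[3]),
                mismatches=int(f[4]), gap_opens=int(f[5]),
                qstart=qstart, qend=qend, sstart=sstart, send=send,
                e_value=e_value, bit_score=float(f[11]),
                raw_score=0.0,
                query_coverage=min(qcov, 1.0), subject_coverage=min(scov, 1.0),
            ))
    return hits


# ---------------------------------------------------------------------------
# Comparison matrix TSV (diagonal = gene counts, upper = ortholog counts,
# lower = mean identities at 2 decimals)
# ---------------------------------------------------------------------------


def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Serialize an AgiosMatrix as a square TSV.

    Header row and column carry the genome IDs. The diagonal holds integer
    gene counts, the upper triangle integer ortholog counts, and the lower
    triangle mean identities formatted to 2 decimal places ('.' decimal
    separator, no thousands separators). Undefined identities are 'NA'.
    """
    ids = matrix.genome_ids
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(ids)) + "\n")
        for i, gi in enumerate(ids):
            row: list[str] = [gi]
            for j in range(len(ids)):
                if i == j:
                    row.append(str(matrix.gene_counts[i]))
                elif i < j:
                    row.append(str(matrix.ortholog_count_at(i, j)))
                else:
                    v = matrix.agios_at(i, j)
                    row.append("NA" if v is None or math.isnan(v)
                               else f"{v:.2f}")
            fh.write("\t".join(row) + "\n")


def read_matrix_tsv(path: str | Path):
    """Read a matrix TSV written by :func:`write_matrix_tsv`."""
    from .agios import AgiosMatrix  # deferred: avoid import cycle

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    ids = header[1:]
    n = len(ids)
    if len(lines) != n + 1:
        raise SeqIOError(f"{path}: expected {n + 1} rows, got {len(lines)}")
    matrix = AgiosMatrix(genome_ids=list(ids), gene_counts=[0] * n)
    for i, line in enumerate(lines[1:]):
        fields = line.split("\t")
        if fields[0] != ids[i]:
            raise SeqIOError(
                f"{path}: row label {fields[0]!r} != column label {ids[i]!r}"
            )
        if len(fields) != n + 1:
            raise SeqIOError(f"{path}: row {ids[i]!r} has wrong width")
        for j, cell in enumerate(fields[1:]):
            if i == j:
                matrix.gene_counts[i] = int(cell)
            elif i < j:
                matrix.set_ortholog_count(i, j, int(cell))
            else:
                matrix.set_agios(i, j,
                                 None if cell == "NA" else float(cell))
    return matrix
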