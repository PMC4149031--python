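"""Genome-level summary statistics, 16S identity with the 98.7% species-
delineation threshold, and COG-category table summarization."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .pairwise import ScoringScheme, nw_align
from .seqio import Assembly, GeneSet, SequenceRecord

import logging

logger = logging.getLogger(__name__)

SPECIES_16S_THRESHOLD = 98.7  # percent 16S identity below which a new
# species may be proposed without DNA-DNA hybridization

COG_CATEGORIES = "JAKLBDYVTMNZWUOCGEFHIPQRS"  # 25 single-letter categories
UNASSIGNED = "-"


class StatsError(ValueError):
    pass


@dataclass
class GenomeStats:
    genome_id: str
    size_bp: int
    gc_pct: float
    coding_bp: Optional[int] = None
    coding_pct: Optional[float] = None
    n_genes: Optional[int] = None
    n_protein_coding: Optional[int] = None
    n_rna: Optional[int] = None  # user-supplied; prediction is out of scope
    n_orfans: Optional[int] = None

    @property
    def orfan_pct(self) -> Optional[float]:
        if self.n_orfans is None or not self.n_protein_coding:
            return None
        return 100.0 * self.n_orfans / self.n_protein_coding

    def as_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "size_bp": self.size_bp,
            "gc_pct": self.gc_pct,
            "coding_bp": self.coding_bp,
            "coding_pct": self.coding_pct,
            "n_genes": self.n_genes,
            "n_protein_coding": self.n_protein_coding,
            "n_rna": self.n_rna,
            "n_orfans": self.n_orfans,
            "orfan_pct": self.orfan_pct,
        }


def genome_size(assembly: Assembly) -> int:
    """Total assembly length: sum of contig lengths, all residues counted
    (ambiguous bases and N included)."""
    return assembly.total_length


def gc_content(assembly: Assembly) -> float:
    """Percent G+C over unambiguous bases: 100*(G+C)/(A+C+G+T)."""
    gc = 0
    acgt = 0
    for contig in assembly.contigs:
        counts = Counter(contig.residues)
        gc += counts["G"] + counts["C"]
        acgt += counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if acgt == 0:
        raise StatsError(
            f"assembly {assembly.genome_id!r} has no unambiguous bases"
        )
    return 100.0 * gc / acgt


def coding_density(assembly: Assembly, geneset: GeneSet
                   ) -> tuple[int, float]:
    """Coding base pairs and percent of the genome they cover.

    ``coding_bp`` is the size of the union of CDS intervals per contig
    (overlapping genes counted once), strand-agnostic. Genes without
    coordinates or out-of-bounds coordinates are errors.
    """
    lengths = assembly.contig_lengths()
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for gene in geneset:
        c = gene.coords
        if c is None:
            raise StatsError(f"gene {gene.gene_id!r} has no coordinates")
        if c.contig_id not in lengths:
            raise StatsError(
                f"gene {gene.gene_id!r}: unknown contig {c.contig_id!r}"
            )
        if c.end > lengths[c.contig_id]:
            raise StatsError(
                f"gene {gene.gene_id!r}: end {c.end} beyond contig "
                f"{c.contig_id!r} length {lengths[c.contig_id]}"
            )
        by_contig.setdefault(c.contig_id, []).append((c.start, c.end))

    coding_bp = 0
    for intervals in by_contig.values():
        intervals.sort()
        cur_start, cur_end = intervals[0]
        for start, end in intervals[1:]:
            if start <= cur_end + 1:
                cur_end = max(cur_end, end)
            else:
                coding_bp += cur_end - cur_start + 1
                cur_start, cur_end = start, end
        coding_bp += cur_end - cur_start + 1

    size = genome_size(assembly)
    return coding_bp, (100.0 * coding_bp / size if size else 0.0)


def sixteen_s_identity(seq1: SequenceRecord, seq2: SequenceRecord,
                       scheme: Optional[ScoringScheme] = None,
                       denominator: str = "all") -> float:
    """Global-alignment percent identity between two 16S rRNA sequences.

    Warns (does not fail) below 500 bp, where partial sequences make the
    estimate unreliable.
    """
    for s in (seq1, seq2):
        if len(s) < 500:
            logger.warning(
                "16S sequence %s is only %d bp; identity may be unreliable",
                s.id, len(s),
            )
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    return nw_align(seq1, seq2, scheme, denominator=denominator).identity_pct


@dataclass(frozen=True)
class DelineationResult:
    seq_id_1: str
    seq_id_2: str
    identity_pct: float
    threshold: float = SPECIES_16S_THRESHOLD

    @property
    def verdict(self) -> str:
        # the criterion is being strictly LOWER than the threshold, so the
        # boundary value itself does not support a new species
        if self.identity_pct < self.threshold:
            return "below_threshold_candidate_new_species"
        return "above_threshold_same_species_not_excluded"

    @property
    def candidate_new_species(self) -> bool:
        return self.identity_pct < self.threshold


def delineate(identity_pct: float, seq_id_1: str = "query",
              seq_id_2: str = "reference",
              threshold: float = SPECIES_16S_THRESHOLD) -> DelineationResult:
    if not (0.0 <= identity_pct <= 100.0):
        raise StatsError("identity_pct must lie in [0, 100]")
    return DelineationResult(seq_id_1, seq_id_2, identity_pct, threshold)


def summarize_cogs(assignments: Mapping[str, str],
                   n_total: Optional[int] = None) -> dict:
    """Per-category gene counts and percentages from a user-supplied
    COG-category table.

    ``assignments`` maps gene_id to one or more category letters (a gene
    with multiple letters counts once per letter); '-' marks genes not in
    COGs. Percentages are over ``n_total`` protein-coding genes (default:
    number of genes in the table).
    """
    counts: Counter = Counter()
    for gene_id, letters in assignments.items():
        if not letters:
            raise StatsError(f"gene {gene_id!r}: empty category string")
        for letter in letters:
            if letter != UNASSIGNED and letter not in COG_CATEGORIES:
                raise StatsError(
                    f"gene {gene_id!r}: unknown COG category {letter!r}"
                )
            counts[letter] += 1
    total = n_total if n_total is not None else len(assignments)
    table = {}
    for letter in COG_CATEGORIES + UNASSIGNED:
        c = counts.get(letter, 0)
        table[letter] = {
            "count": c,
            "pct": (100.0 * c / total) if total else 0.0,
        }
    return {"total_genes": total, "categories": table}
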