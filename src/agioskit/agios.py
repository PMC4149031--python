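"""Mean nucleotide identity over orthologous genes (AGIOS).

For a genome pair: all-vs-all protein search, reciprocal-best-hit pairing,
then a global nucleotide alignment of each ortholog pair's CDS sequences.
The pair statistic is the unweighted mean of the per-pair percent
identities; a length-weighted variant is available behind a flag. Multi-
genome runs assemble a square matrix whose diagonal holds gene counts,
upper triangle shared-ortholog counts, lower triangle mean identities.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .orthology import (
    OrthologPair,
    SignificanceRule,
    all_vs_all,
    reciprocal_best_hits,
)
from .pairwise import ScoringScheme, nw_align
from .seqio import GeneSet


class AgiosError(ValueError):
    pass


@dataclass(frozen=True)
class AgiosConfig:
    """Knobs for a comparison run; defaults follow common practice for
    RBH-based ortholog calling (identity >= 25%, coverage >= 50%,
    search keep-threshold E <= 1e-05)."""

    protein_scheme: ScoringScheme = field(
        default_factory=ScoringScheme.protein
    )
    nucleotide_scheme: ScoringScheme = field(
        default_factory=ScoringScheme.nucleotide
    )
    rule: SignificanceRule = field(default_factory=SignificanceRule)
    min_identity: float = 25.0
    min_coverage: float = 0.5
    min_evalue_keep: float = 1e-05
    exact_search: bool = False
    kmer_k: int = 5
    identity_denominator: str = "all"  # "all" | "aligned"
    length_weighted: bool = False
    threads: int = 1


@dataclass
class PairComparison:
    """Result of one genome-pair comparison."""

    genome_a: str
    genome_b: str
    pairs: list[OrthologPair]

    @property
    def n_orthologs(self) -> int:
        return len(self.pairs)

    def agios_pct(self, length_weights: Optional[Sequence[float]] = None
                  ) -> Optional[float]:
        """Unweighted mean identity over ortholog pairs; None (NA) when
        there are no orthologs. Pass weights for the length-weighted mode."""
        if not self.pairs:
            return None
        idents = [p.nt_identity_pct for p in self.pairs]
        if any(v is None for v in idents):
            raise AgiosError("ortholog pairs missing nucleotide identities")
        if length_weights is None:
            return sum(idents) / len(idents)
        if len(length_weights) != len(idents):
            raise AgiosError("one weight per ortholog pair required")
        total = sum(length_weights)
        return sum(w * v for w, v in zip(length_weights, idents)) / total


def compare_pair(set_a: GeneSet, set_b: GeneSet,
                 config: Optional[AgiosConfig] = None) -> PairComparison:
    """Compare two genomes: search, RBH pairing, and per-pair global
    nucleotide identity. Deterministic given the config."""
    if config is None:
        config = AgiosConfig()
    hits = all_vs_all(
        set_a, set_b, scheme=config.protein_scheme,
        min_evalue_keep=config.min_evalue_keep,
        exact=config.exact_search, kmer_k=config.kmer_k,
    )
    skeletons = reciprocal_best_hits(
        hits, rule=config.rule,
        min_identity=config.min_identity, min_coverage=config.min_coverage,
        genes_a=set_a.gene_ids, genes_b=set_b.gene_ids,
    )
    genes_a = {g.gene_id: g for g in set_a}
    genes_b = {g.gene_id: g for g in set_b}

    def ident(pair: OrthologPair) -> float:
        aln = nw_align(
            genes_a[pair.gene_a].cds, genes_b[pair.gene_b].cds,
            scheme=config.nucleotide_scheme,
            denominator=config.identity_denominator,
        )
        return aln.identity_pct

    if config.threads > 1 and len(skeletons) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            idents = list(pool.map(ident, skeletons))
    else:
        idents = [ident(p) for p in skeletons]

    pairs = [
        replace(p, nt_identity_pct=v) for p, v in zip(skeletons, idents)
    ]
    return PairComparison(
        genome_a=set_a.genome_id, genome_b=set_b.genome_id, pairs=pairs
    )


@dataclass
class AgiosMatrix:
    """Square multi-genome summary: diagonal gene counts, upper-triangle
    shared ortholog counts, lower-triangle mean identities (stored at full
    precision; rounding happens only at serialization)."""

    genome_ids: list[str]
    gene_counts: list[int]
    _orth: dict[tuple[int, int], int] = field(default_factory=dict)
    _agios: dict[tuple[int, int], Optional[float]] = field(
        default_factory=dict
    )

    def _index(self, genome_id: str) -> int:
        try:
            return self.genome_ids.index(genome_id)
        except ValueError:
            raise AgiosError(f"unknown genome {genome_id!r}") from None

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        if i == j:
            raise AgiosError("no off-diagonal cell for a genome with itself")
        return (i, j) if i < j else (j, i)

    def set_ortholog_count(self, i: int, j: int, count: int) -> None:
        self._orth[self._key(i, j)] = count

    def set_agios(self, i: int, j: int, value: Optional[float]) -> None:
        self._agios[self._key(i, j)] = value

    def ortholog_count_at(self, i: int, j: int) -> int:
        return self._orth[self._key(i, j)]

    def agios_at(self, i: int, j: int) -> Optional[float]:
        return self._agios[self._key(i, j)]

    def ortholog_count(self, a: str, b: str) -> int:
        return self.ortholog_count_at(self._index(a), self._index(b))

    def agios(self, a: str, b: str) -> Optional[float]:
        return self.agios_at(self._index(a), self._index(b))

    def gene_count(self, a: str) -> int:
        return self.gene_counts[self._index(a)]

    def validate(self) -> None:
        n = len(self.genome_ids)
        for i in range(n):
            for j in range(i + 1, n):
                c = self._orth[(i, j)]
                if c > min(self.gene_counts[i], self.gene_counts[j]):
                    raise AgiosError(
                        "ortholog count exceeds smaller gene count for "
                        f"{self.genome_ids[i]} vs {self.genome_ids[j]}"
                    )
                v = self._agios[(i, j)]
                if v is not None and not (0.0 <= v <= 100.0):
                    raise AgiosError("mean identity outside [0, 100]")


def build_matrix(genesets: Sequence[GeneSet],
                 config: Optional[AgiosConfig] = None) -> AgiosMatrix:
    """Compare all genome pairs and assemble the summary matrix."""
    if len(genesets) < 2:
        raise AgiosError("need at least 2 genomes")
    ids = [gs.genome_id for gs in genesets]
    if len(set(ids)) != len(ids):
        raise AgiosError("duplicate genome IDs")
    matrix = AgiosMatrix(
        genome_ids=list(ids), gene_counts=[len(gs) for gs in genesets]
    )
    for i in range(len(genesets)):
        for j in range(i + 1, len(genesets)):
            cmpres = compare_pair(genesets[i], genesets[j], config)
            matrix.set_ortholog_count(i, j, cmpres.n_orthologs)
            matrix.set_agios(i, j, cmpres.agios_pct())
    matrix.validate()
    return matrix


def agios_range_report(matrix: AgiosMatrix,
                       focal: Optional[str] = None) -> dict:
    """Min/max of the filled mean identities, overall and (optionally)
    restricted to pairs involving a focal genome."""
    n = len(matrix.genome_ids)
    values = [
        v for (i, j), v in sorted(matrix._agios.items()) if v is not None
    ]
    report: dict = {
        "n_genomes": n,
        "overall": _min_max(values),
    }
    if focal is not None:
        fi = matrix._index(focal)
        focal_vals = [
            v for (i, j), v in sorted(matrix._agios.items())
            if v is not None and fi in (i, j)
        ]
        report["focal_genome"] = focal
        report["vs_focal"] = _min_max(focal_vals)
    return report


def _min_max(values: list[float]) -> dict:
    if not values:
        return {"min": None, "max": None, "n_values": 0}
    return {
        "min": min(values), "max": max(values), "n_values": len(values)
    }
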