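"""Ortholog detection between two annotated genomes.

All-vs-all protein similarity search (exact Smith–Waterman, optionally
behind a shared-k-mer prefilter), strict 1:1 reciprocal-best-hit pairing,
and ORFan classification under a two-tier E-value/alignment-length rule:
significant means E < 1e-03 for alignments longer than 80 aa, or E < 1e-05
at 80 aa and below.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .pairwise import (
    KarlinAltschulParams,
    ScoringScheme,
    bit_score,
    evalue,
    sw_align,
)
from .seqio import GeneSet


class OrthologyError(ValueError):
    pass


@dataclass(frozen=True)
class HomologyHit:
    """A scored query -> subject protein similarity record."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float
    alignment_length: int  # aligned columns, in amino acids
    identity_pct: float
    query_coverage: float  # aligned span / sequence length, in [0, 1]
    subject_coverage: float
    mismatches: int = 0
    gap_opens: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise OrthologyError("E-value must be positive")
        if not (0 <= self.identity_pct <= 100):
            raise OrthologyError("identity_pct outside [0, 100]")
        if not (0 <= self.query_coverage <= 1 and
                0 <= self.subject_coverage <= 1):
            raise OrthologyError("coverages must lie in [0, 1]")
        if self.alignment_length < 1:
            raise OrthologyError("alignment_length must be >= 1")


@dataclass(frozen=True)
class OrthologPair:
    """A 1:1 ortholog pair; nt_identity_pct is filled from the global
    alignment of the paired CDS sequences."""

    gene_a: str
    gene_b: str
    nt_identity_pct: Optional[float] = None


@dataclass(frozen=True)
class SignificanceRule:
    """Two-tier homology significance cutoffs.

    Alignments longer than ``length_cut`` amino acids are significant below
    ``e_long``; shorter alignments must clear the stricter ``e_short``.
    """

    e_long: float = 1e-03
    e_short: float = 1e-05
    length_cut: int = 80

    def __post_init__(self) -> None:
        if not self.e_short < self.e_long:
            raise OrthologyError("require e_short < e_long")
        if self.length_cut <= 0:
            raise OrthologyError("length_cut must be positive")


def is_significant(hit: HomologyHit, rule: SignificanceRule) -> bool:
    """True iff the hit clears the length-conditional E-value cutoff."""
    if hit.alignment_length > rule.length_cut:
        return hit.e_value < rule.e_long
    return hit.e_value < rule.e_short


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _count_gap_opens(aligned: str) -> int:
    opens = 0
    in_gap = False
    for ch in aligned:
        if ch == "-":
            if not in_gap:
                opens += 1
            in_gap = True
        else:
            in_gap = False
    return opens


def _hit_from_alignment(qid: str, sid: str, aln, qlen: int, slen: int,
                        search_space_n: int, scheme: ScoringScheme
                        ) -> HomologyHit:
    params = KarlinAltschulParams(
        lambda_=scheme.ka_lambda, k=scheme.ka_k, m=qlen, n=search_space_n
    )
    e = max(evalue(aln.score, params), 1e-300)
    aligned_cols = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x != "-" and y != "-"
    )
    mismatches = aligned_cols - aln.identities
    return HomologyHit(
        query_id=qid, subject_id=sid,
        raw_score=aln.score,
        bit_score=bit_score(aln.score, scheme.ka_lambda, scheme.ka_k),
        e_value=e,
        alignment_length=aln.columns,
        identity_pct=100.0 * aln.identities / aln.columns,
        query_coverage=(aln.a_end - aln.a_start + 1) / qlen,
        subject_coverage=(aln.b_end - aln.b_start + 1) / slen,
        mismatches=mismatches,
        gap_opens=_count_gap_opens(aln.aligned_a) +
        _count_gap_opens(aln.aligned_b),
        qstart=aln.a_start, qend=aln.a_end,
        sstart=aln.b_start, send=aln.b_end,
    )


def all_vs_all(set_a: GeneSet, set_b: GeneSet,
               scheme: Optional[ScoringScheme] = None,
               min_evalue_keep: float = 1e-05,
               exact: bool = False,
               kmer_k: int = 5) -> list[HomologyHit]:
    """Exact protein similarity search between two gene sets.

    Every (a, b) pair whose best local (Smith–Waterman) alignment has
    E-value <= ``min_evalue_keep`` yields one :class:`HomologyHit`. With
    ``exact=False`` a shared-k-mer prefilter skips pairs whose proteins
    share no exact k-mer (default k=5); such pairs essentially never reach
    the keep threshold, and prefilter and exact modes must agree on all
    kept hits.

    E-values use m = query length and n = total residues in the subject
    gene set (database-style search space).
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise OrthologyError("gene sets must be non-empty")
    if scheme is None:
        scheme = ScoringScheme.protein()

    n_db = sum(len(g.protein) for g in set_b)
    subject_kmers = None
    if not exact:
        subject_kmers = {
            g.gene_id: _kmers(g.protein.residues, kmer_k) for g in set_b
        }

    hits: list[HomologyHit] = []
    for ga in set_a:
        qseq = ga.protein.residues
        q_kmers = _kmers(qseq, kmer_k) if not exact else None
        for gb in set_b:
            if subject_kmers is not None and not (
                q_kmers & subject_kmers[gb.gene_id]
            ):
                continue
            aln = sw_align(ga.protein, gb.protein, scheme)
            if aln.is_empty:
                continue
            hit = _hit_from_alignment(
                ga.gene_id, gb.gene_id, aln,
                len(ga.protein), len(gb.protein), n_db, scheme,
            )
            if hit.e_value <= min_evalue_keep:
                hits.append(hit)
    return hits


def _hit_order_key(hit: HomologyHit):
    # best = max bit score; ties by lower E-value, then lexicographic
    # partner ID — fully deterministic
    return (-hit.bit_score, hit.e_value, hit.subject_id)


def _best_partner(hits_by_gene: dict[str, list[HomologyHit]]
                  ) -> dict[str, str]:
    best: dict[str, str] = {}
    for gene, hits in hits_by_gene.items():
        best[gene] = min(hits, key=_hit_order_key).subject_id
    return best


def reciprocal_best_hits(hits: Sequence[HomologyHit],
                         rule: Optional[SignificanceRule] = None,
                         min_identity: float = 25.0,
                         min_coverage: float = 0.5,
                         genes_a: Optional[Iterable[str]] = None,
                         genes_b: Optional[Iterable[str]] = None
                         ) -> list[OrthologPair]:
    """Strict 1:1 reciprocal-best-hit pairing.

    ``hits`` must contain the hits of A-vs-B and/or B-vs-A for one ordered
    genome pair; each direction is recovered from query membership when
    ``genes_a``/``genes_b`` are given, otherwise A-queries are inferred from
    the A-vs-B orientation of the input (queries seen first). Hits are
    filtered by the significance rule, ``min_identity`` (percent) and
    ``min_coverage`` (on both sequences) before best hits are taken.

    A pair (a, b) is returned iff b is a's best surviving hit in B and a is
    b's best surviving hit in A, under the deterministic ordering
    (bit score desc, E-value asc, partner ID asc).
    """
    if rule is None:
        rule = SignificanceRule()

    kept = [
        h for h in hits
        if is_significant(h, rule)
        and h.identity_pct >= min_identity
        and h.query_coverage >= min_coverage
        and h.subject_coverage >= min_coverage
    ]
    if not kept:
        return []

    if genes_a is not None and genes_b is not None:
        a_ids, b_ids = set(genes_a), set(genes_b)
    else:
        # single-direction table: queries are genome A, subjects genome B
        a_ids = {h.query_id for h in hits}
        b_ids = {h.subject_id for h in hits}
        if a_ids & b_ids:
            raise OrthologyError(
                "ambiguous genome membership: pass genes_a/genes_b when "
                "gene IDs overlap or hits mix directions"
            )

    fwd: dict[str, list[HomologyHit]] = {}
    rev: dict[str, list[HomologyHit]] = {}
    for h in kept:
        if h.query_id in a_ids and h.subject_id in b_ids:
            fwd.setdefault(h.query_id, []).append(h)
            # symmetric scores: an A-vs-B table alone supports RBH
            rev.setdefault(h.subject_id, []).append(_flip(h))
        elif h.query_id in b_ids and h.subject_id in a_ids:
            rev.setdefault(h.query_id, []).append(h)
            fwd.setdefault(h.subject_id, []).append(_flip(h))
        else:
            raise OrthologyError(
                f"hit {h.query_id}->{h.subject_id} spans genes outside the "
                "declared genome pair"
            )

    best_a = _best_partner(fwd)
    best_b = _best_partner(rev)
    pairs = [
        OrthologPair(gene_a=a, gene_b=b)
        for a, b in best_a.items()
        if best_b.get(b) == a
    ]
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def _flip(h: HomologyHit) -> HomologyHit:
    return HomologyHit(
        query_id=h.subject_id, subject_id=h.query_id,
        raw_score=h.raw_score, bit_score=h.bit_score, e_value=h.e_value,
        alignment_length=h.alignment_length, identity_pct=h.identity_pct,
        query_coverage=h.subject_coverage,
        subject_coverage=h.query_coverage,
        mismatches=h.mismatches, gap_opens=h.gap_opens,
        qstart=h.sstart, qend=h.send, sstart=h.qstart, send=h.qend,
    )


def classify_orfans(geneset: GeneSet, hits_vs_reference: Sequence[HomologyHit],
                    rule: Optional[SignificanceRule] = None) -> set[str]:
    """Gene IDs with no significant homolog in the reference search.

    A gene is an ORFan iff none of its hits clears the significance rule;
    genes with zero hits are ORFans.
    """
    if rule is None:
        rule = SignificanceRule()
    gene_ids = set(geneset.gene_ids)
    unknown = {h.query_id for h in hits_vs_reference} - gene_ids
    if unknown:
        raise OrthologyError(
            f"hit table queries not in gene set: {sorted(unknown)[:5]}"
        )
    with_homolog = {
        h.query_id for h in hits_vs_reference if is_significant(h, rule)
    }
    return gene_ids - with_homolog
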