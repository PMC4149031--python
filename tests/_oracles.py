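"""Independent reference implementations used as test oracles.

These deliberately avoid the package's Gotoh three-state recurrence and RBH
bookkeeping: alignment scores come from a gap-length-enumeration DP (and,
for tiny inputs, literal enumeration of every alignment), RBH pairs from a
definition-level quadratic check.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

NEG = float("-inf")


def gap_cost(length: int, gap_open: float, gap_extend: float) -> float:
    return gap_open + (length - 1) * gap_extend


def global_score_oracle(a: str, b: str, score: Callable[[str, str], float],
                        gap_open: float, gap_extend: float) -> float:
    """Global affine-gap optimum via explicit enumeration of gap lengths.

    G[i][j] = best score aligning a[:i] with b[:j]; every maximal gap run
    of length g is charged gap_cost(g) in one step.
    """
    la, lb = len(a), len(b)
    g = [[NEG] * (lb + 1) for _ in range(la + 1)]
    g[0][0] = 0.0
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            best = NEG
            if i > 0 and j > 0:
                best = g[i - 1][j - 1] + score(a[i - 1], b[j - 1])
            for k in range(1, i + 1):
                cand = g[i - k][j] - gap_cost(k, gap_open, gap_extend)
                if cand > best:
                    best = cand
            for k in range(1, j + 1):
                cand = g[i][j - k] - gap_cost(k, gap_open, gap_extend)
                if cand > best:
                    best = cand
            g[i][j] = best
    return g[la][lb]


def local_score_oracle(a: str, b: str, score: Callable[[str, str], float],
                       gap_open: float, gap_extend: float) -> float:
    """Local affine-gap optimum: gap-length-enumeration DP with zero clamp;
    the empty alignment scores 0."""
    la, lb = len(a), len(b)
    h = [[0.0] * (lb + 1) for _ in range(la + 1)]
    best_all = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best = h[i - 1][j - 1] + score(a[i - 1], b[j - 1])
            for k in range(1, i + 1):
                cand = h[i - k][j] - gap_cost(k, gap_open, gap_extend)
                if cand > best:
                    best = cand
            for k in range(1, j + 1):
                cand = h[i][j - k] - gap_cost(k, gap_open, gap_extend)
                if cand > best:
                    best = cand
            h[i][j] = max(0.0, best)
            best_all = max(best_all, h[i][j])
    return best_all


def enumerate_global_score(a: str, b: str, score: Callable[[str, str], float],
                           gap_open: float, gap_extend: float) -> float:
    """Literal enumeration of every global alignment (tiny inputs only)."""
    best = [NEG]

    def walk(i: int, j: int, acc: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], acc)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, acc + score(a[i], b[j]), "D")
        if i < len(a):
            cost = gap_extend if prev == "U" else gap_open
            walk(i + 1, j, acc - cost, "U")
        if j < len(b):
            cost = gap_extend if prev == "L" else gap_open
            walk(i, j + 1, acc - cost, "L")

    walk(0, 0, 0.0, "D")
    return best[0]


def simple_score_fn(match: float, mismatch: float) -> Callable:
    return lambda x, y: match if x == y else mismatch


# ---------------------------------------------------------------------------
# RBH oracle
# ---------------------------------------------------------------------------


def hit_passes(hit, rule, min_identity: float, min_coverage: float) -> bool:
    if hit.alignment_length > rule.length_cut:
        sig = hit.e_value < rule.e_long
    else:
        sig = hit.e_value < rule.e_short
    return (sig and hit.identity_pct >= min_identity
            and hit.query_coverage >= min_coverage
            and hit.subject_coverage >= min_coverage)


def _beats(h1, h2) -> bool:
    """True iff h1 strictly precedes h2 in (bit desc, E asc, partner asc)."""
    k1 = (-h1.bit_score, h1.e_value, h1.subject_id)
    k2 = (-h2.bit_score, h2.e_value, h2.subject_id)
    return k1 < k2


def rbh_oracle(hits: Sequence, rule, min_identity: float,
               min_coverage: float, a_ids: set, b_ids: set) -> set:
    """Definition-level reciprocal-best check over A->B hit tables.

    ``hits`` must be A-query oriented; the reverse direction is implied by
    score symmetry (as in the implementation under test).
    """
    kept = [h for h in hits if hit_passes(h, rule, min_identity, min_coverage)]
    pairs = set()
    for h in kept:
        a, b = h.query_id, h.subject_id
        # b must beat every other surviving hit of query a
        best_for_a = all(
            _beats(h, other) for other in kept
            if other.query_id == a and other.subject_id != b
        )
        # a must beat every other surviving query hitting subject b
        import types

        def flipped(x):
            return types.SimpleNamespace(
                bit_score=x.bit_score, e_value=x.e_value,
                subject_id=x.query_id,
            )

        best_for_b = all(
            _beats(flipped(h), flipped(other)) for other in kept
            if other.subject_id == b and other.query_id != a
        )
        if best_for_a and best_for_b:
            pairs.add((a, b))
    return pairs


# ---------------------------------------------------------------------------
# Simulation expectation
# ---------------------------------------------------------------------------


def expected_identity_fraction(p_sub: float, ts_tv_ratio: float) -> float:
    """Closed-form expected per-site identity between two descendants.

    Given a substitution, a lineage picks the transition partner with
    probability kappa / (kappa + 1), so two substituted lineages collide on
    the same base with probability c = p_ts^2 + 2 p_tv^2. The simulator
    calibrates its per-lineage rate q so that (1-q)^2 + c q^2 = 1 - p_sub;
    this oracle recomputes that identity from q independently.
    """
    kappa = ts_tv_ratio
    p_ts = kappa / (kappa + 1.0)
    p_tv_each = (1.0 - p_ts) / 2.0
    collide = p_ts ** 2 + 2.0 * p_tv_each ** 2
    q = (1.0 - math.sqrt(1.0 - (1.0 + collide) * p_sub)) / (1.0 + collide)
    return (1.0 - q) ** 2 + (q ** 2) * collide


def coding_bp_bruteforce(contig_lengths: dict, intervals: list) -> int:
    """Per-base membership count: intervals are (contig, start, end)
    1-based inclusive."""
    covered = 0
    for contig, length in contig_lengths.items():
        marks = [False] * (length + 1)
        for c, s, e in intervals:
            if c != contig:
                continue
            for pos in range(s, e + 1):
                marks[pos] = True
        covered += sum(marks)
    return covered
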