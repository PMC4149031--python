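"""Pairwise sequence alignment: global (Needleman–Wunsch) and local
(Smith–Waterman) alignment with affine gaps, percent identity, and
Karlin–Altschul E-value estimation.

Gap model: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(the first gapped residue pays the opening cost). Traceback ties are broken
deterministically: diagonal > up (gap in b) > left (gap in a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .seqio import SequenceRecord

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


NT_LETTERS = "ACGTNRYSWKMBDHV"
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWYX*"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin–Altschul constants.

    Nucleotide default follows the EMBOSS-needle convention (match +5,
    mismatch -4, gap open 10, gap extend 0.5). Protein default is BLOSUM62
    with gap open 11 / extend 1 and the standard gapped constants
    lambda = 0.267, K = 0.041 so internal E-values are comparable to
    BLASTP thresholds.
    """

    kind: str  # "nucleotide" | "protein"
    match: float = 5.0
    mismatch: float = -4.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def __post_init__(self) -> None:
        if self.kind not in ("nucleotide", "protein"):
            raise AlignmentError(f"unknown scheme kind {self.kind!r}")
        if not (self.gap_open >= self.gap_extend > 0):
            raise AlignmentError("require gap_open >= gap_extend > 0")

    @classmethod
    def nucleotide(cls, match: float = 5.0, mismatch: float = -4.0,
                   gap_open: float = 10.0, gap_extend: float = 0.5
                   ) -> "ScoringScheme":
        # nominal gapped +5/-4 constants; nucleotide E-values are not used
        # by the ortholog pipeline
        return cls(kind="nucleotide", match=match, mismatch=mismatch,
                   gap_open=gap_open, gap_extend=gap_extend,
                   ka_lambda=0.192, ka_k=0.176)

    @classmethod
    def protein(cls, matrix_name: str = "BLOSUM62", gap_open: float = 11.0,
                gap_extend: float = 1.0) -> "ScoringScheme":
        return cls(kind="protein", matrix_name=matrix_name,
                   gap_open=gap_open, gap_extend=gap_extend,
                   ka_lambda=0.267, ka_k=0.041)

    @property
    def letters(self) -> str:
        return NT_LETTERS if self.kind == "nucleotide" else AA_LETTERS

    def substitution_matrix(self) -> np.ndarray:
        if self.kind == "nucleotide":
            return _nt_matrix(self.match, self.mismatch)
        return _aa_matrix(self.matrix_name)

    def encoder(self) -> np.ndarray:
        return _encoder_for(self.letters)


@lru_cache(maxsize=None)
def _nt_matrix(match: float, mismatch: float) -> np.ndarray:
    n = len(NT_LETTERS)
    m = np.full((n, n), mismatch, dtype=np.float64)
    np.fill_diagonal(m, match)
    return m


@lru_cache(maxsize=None)
def _aa_matrix(name: str) -> np.ndarray:
    from Bio.Align import substitution_matrices

    sm = substitution_matrices.load(name)
    n = len(AA_LETTERS)
    out = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(AA_LETTERS):
        for j, b in enumerate(AA_LETTERS):
            out[i, j] = sm[a, b]
    return out


@lru_cache(maxsize=None)
def _encoder_for(letters: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int64)
    for i, ch in enumerate(letters):
        lut[ord(ch)] = i
    return lut


def encode(seq: str, scheme: ScoringScheme) -> np.ndarray:
    lut = scheme.encoder()
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = int(np.argmax(arr < 0))
        raise AlignmentError(
            f"residue {seq[bad]!r} at position {bad + 1} not scorable "
            f"under {scheme.kind} scheme"
        )
    return arr


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment with score and identity accounting.

    ``identity_pct`` uses ``denominator``: "all" divides identities by every
    alignment column (gaps included); "aligned" divides by gap-free columns
    only.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identities: int
    columns: int
    identity_pct: float
    denominator: str = "all"
    # 1-based inclusive spans of the aligned regions (0 for empty alignment)
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    @property
    def is_empty(self) -> bool:
        return self.columns == 0


def _identity_stats(aligned_a: str, aligned_b: str, denominator: str
                    ) -> tuple[int, int, float]:
    columns = len(aligned_a)
    identities = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    if denominator == "all":
        denom = columns
    elif denominator == "aligned":
        denom = sum(
            1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"
        )
    else:
        raise AlignmentError(f"unknown identity denominator {denominator!r}")
    pct = 100.0 * identities / denom if denom else 0.0
    return identities, columns, pct


def _coerce(seq, scheme: ScoringScheme) -> str:
    if isinstance(seq, SequenceRecord):
        if seq.alphabet != scheme.kind:
            raise AlignmentError(
                f"record {seq.id!r} has alphabet {seq.alphabet!r}; scheme "
                f"expects {scheme.kind!r}"
            )
        return seq.residues
    return str(seq)


def _check_pair(a, b) -> None:
    if isinstance(a, SequenceRecord) and isinstance(b, SequenceRecord):
        if a.alphabet != b.alphabet:
            raise AlignmentError(
                f"mixed alphabets: {a.alphabet!r} vs {b.alphabet!r}"
            )


# ---------------------------------------------------------------------------
# DP kernels (Gotoh, three states). State codes: 0 = M (diagonal),
# 1 = X (gap in b, consume a: "up"), 2 = Y (gap in a, consume b: "left"),
# 3 = STOP (local alignment start).
# ---------------------------------------------------------------------------

NEG = -1e30


@njit(cache=True, nogil=True)
def _nw_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    la, lb = a.shape[0], b.shape[0]
    m_prev = np.empty(lb + 1, np.float64)
    x_prev = np.empty(lb + 1, np.float64)
    y_prev = np.empty(lb + 1, np.float64)
    m_cur = np.empty(lb + 1, np.float64)
    x_cur = np.empty(lb + 1, np.float64)
    y_cur = np.empty(lb + 1, np.float64)
    ptr_m = np.zeros((la + 1, lb + 1), np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), np.int8)

    m_prev[0] = 0.0
    x_prev[0] = NEG
    y_prev[0] = NEG
    for j in range(1, lb + 1):
        m_prev[j] = NEG
        x_prev[j] = NEG
        y_prev[j] = -(gap_open + (j - 1) * gap_extend)
        ptr_y[0, j] = 0 if j == 1 else 2

    for i in range(1, la + 1):
        m_cur[0] = NEG
        y_cur[0] = NEG
        x_cur[0] = -(gap_open + (i - 1) * gap_extend)
        ptr_x[i, 0] = 0 if i == 1 else 1
        for j in range(1, lb + 1):
            # M: diagonal move, predecessor any state at (i-1, j-1)
            best = m_prev[j - 1]
            p = 0
            if x_prev[j - 1] > best:
                best = x_prev[j - 1]
                p = 1
            if y_prev[j - 1] > best:
                best = y_prev[j - 1]
                p = 2
            m_cur[j] = best + sub[a[i - 1], b[j - 1]]
            ptr_m[i, j] = p
            # X: up move (gap in b), predecessor at (i-1, j)
            best = m_prev[j] - gap_open
            p = 0
            if x_prev[j] - gap_extend > best:
                best = x_prev[j] - gap_extend
                p = 1
            if y_prev[j] - gap_open > best:
                best = y_prev[j] - gap_open
                p = 2
            x_cur[j] = best
            ptr_x[i, j] = p
            # Y: left move (gap in a), predecessor at (i, j-1)
            best = m_cur[j - 1] - gap_open
            p = 0
            if x_cur[j - 1] - gap_open > best:
                best = x_cur[j - 1] - gap_open
                p = 1
            if y_cur[j - 1] - gap_extend > best:
                best = y_cur[j - 1] - gap_extend
                p = 2
            y_cur[j] = best
            ptr_y[i, j] = p
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev

    score = m_prev[lb]
    state = 0
    if x_prev[lb] > score:
        score = x_prev[lb]
        state = 1
    if y_prev[lb] > score:
        score = y_prev[lb]
        state = 2
    return score, state, ptr_m, ptr_x, ptr_y


@njit(cache=True, nogil=True)
def _sw_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    la, lb = a.shape[0], b.shape[0]
    m_prev = np.zeros(lb + 1, np.float64)
    x_prev = np.full(lb + 1, NEG, np.float64)
    y_prev = np.full(lb + 1, NEG, np.float64)
    m_cur = np.zeros(lb + 1, np.float64)
    x_cur = np.full(lb + 1, NEG, np.float64)
    y_cur = np.full(lb + 1, NEG, np.float64)
    ptr_m = np.full((la + 1, lb + 1), 3, np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), np.int8)

    best_score = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, la + 1):
        m_cur[0] = 0.0
        x_cur[0] = NEG
        y_cur[0] = NEG
        for j in range(1, lb + 1):
            best = m_prev[j - 1]
            p = 0
            if x_prev[j - 1] > best:
                best = x_prev[j - 1]
                p = 1
            if y_prev[j - 1] > best:
                best = y_prev[j - 1]
                p = 2
            if best <= 0.0:
                best = 0.0  # fresh start: no prior contribution
                p = 3
            v = best + sub[a[i - 1], b[j - 1]]
            if v < 0.0:
                v = 0.0
                p = 3
            m_cur[j] = v
            ptr_m[i, j] = p

            best = m_prev[j] - gap_open
            p = 0
            if x_prev[j] - gap_extend > best:
                best = x_prev[j] - gap_extend
                p = 1
            if y_prev[j] - gap_open > best:
                best = y_prev[j] - gap_open
                p = 2
            x_cur[j] = best
            ptr_x[i, j] = p

            best = m_cur[j - 1] - gap_open
            p = 0
            if x_cur[j - 1] - gap_open > best:
                best = x_cur[j - 1] - gap_open
                p = 1
            if y_cur[j - 1] - gap_extend > best:
                best = y_cur[j - 1] - gap_extend
                p = 2
            y_cur[j] = best
            ptr_y[i, j] = p

            if m_cur[j] > best_score:
                best_score = m_cur[j]
                best_i = i
                best_j = j
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev

    return best_score, best_i, best_j, ptr_m, ptr_x, ptr_y


def _traceback(sa: str, sb: str, i: int, j: int, state: int,
               ptr_m, ptr_x, ptr_y, local: bool) -> tuple[str, str, int, int]:
    """Walk pointers back from (i, j, state); returns aligned strings plus
    the 1-based start positions in a and b."""
    out_a: list[str] = []
    out_b: list[str] = []
    while True:
        if not local and i == 0 and j == 0:
            break
        if state == 0:
            p = ptr_m[i, j]
            if local and p == 3:
                out_a.append(sa[i - 1])
                out_b.append(sb[j - 1])
                i -= 1
                j -= 1
                break
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
            state = p
        elif state == 1:
            p = ptr_x[i, j]
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
            state = p
        else:
            p = ptr_y[i, j]
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
            state = p
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i + 1, j + 1


def nw_align(a, b, scheme: Optional[ScoringScheme] = None,
             denominator: str = "all") -> AlignmentResult:
    """Optimal global alignment under affine gaps (Gotoh algorithm).

    Accepts :class:`SequenceRecord` or plain strings. Deterministic
    traceback with tie-break diagonal > up > left.
    """
    _check_pair(a, b)
    if scheme is None:
        scheme = _default_scheme(a, b)
    sa, sb = _coerce(a, scheme), _coerce(b, scheme)
    if not sa or not sb:
        raise AlignmentError("cannot align empty sequences")
    ea, eb = encode(sa, scheme), encode(sb, scheme)
    score, state, ptr_m, ptr_x, ptr_y = _nw_fill(
        ea, eb, scheme.substitution_matrix(),
        float(scheme.gap_open), float(scheme.gap_extend),
    )
    al_a, al_b, _, _ = _traceback(sa, sb, len(sa), len(sb), state,
                                  ptr_m, ptr_x, ptr_y, local=False)
    identities, columns, pct = _identity_stats(al_a, al_b, denominator)
    return AlignmentResult(
        aligned_a=al_a, aligned_b=al_b, score=float(score),
        identities=identities, columns=columns, identity_pct=pct,
        denominator=denominator,
        a_start=1, a_end=len(sa), b_start=1, b_end=len(sb),
    )


def sw_align(a, b, scheme: Optional[ScoringScheme] = None,
             denominator: str = "all") -> AlignmentResult:
    """Optimal local alignment under affine gaps.

    An empty alignment (score 0) is returned when no positive-scoring local
    alignment exists.
    """
    _check_pair(a, b)
    if scheme is None:
        scheme = _default_scheme(a, b)
    sa, sb = _coerce(a, scheme), _coerce(b, scheme)
    if not sa or not sb:
        raise AlignmentError("cannot align empty sequences")
    ea, eb = encode(sa, scheme), encode(sb, scheme)
    score, bi, bj, ptr_m, ptr_x, ptr_y = _sw_fill(
        ea, eb, scheme.substitution_matrix(),
        float(scheme.gap_open), float(scheme.gap_extend),
    )
    if score <= 0.0:
        return AlignmentResult(
            aligned_a="", aligned_b="", score=0.0, identities=0, columns=0,
            identity_pct=0.0, denominator=denominator,
        )
    al_a, al_b, a_start, b_start = _traceback(
        sa, sb, int(bi), int(bj), 0, ptr_m, ptr_x, ptr_y, local=True
    )
    identities, columns, pct = _identity_stats(al_a, al_b, denominator)
    return AlignmentResult(
        aligned_a=al_a, aligned_b=al_b, score=float(score),
        identities=identities, columns=columns, identity_pct=pct,
        denominator=denominator,
        a_start=a_start, a_end=int(bi), b_start=b_start, b_end=int(bj),
    )


def _default_scheme(a, b) -> ScoringScheme:
    if isinstance(a, SequenceRecord):
        return (ScoringScheme.nucleotide() if a.alphabet == "nucleotide"
                else ScoringScheme.protein())
    return ScoringScheme.nucleotide()


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Parameters of the E = K * m * n * exp(-lambda * S) model.

    Effective lengths m and n are taken as raw sequence / search-space
    lengths (no edge-effect correction).
    """

    lambda_: float
    k: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k <= 0:
            raise AlignmentError("lambda and K must be positive")
        if self.m < 1 or self.n < 1:
            raise AlignmentError("effective lengths must be >= 1")


def evalue(raw_score: float, params: KarlinAltschulParams) -> float:
    """Expected chance-hit count for a raw alignment score."""
    if not math.isfinite(raw_score):
        raise AlignmentError("raw score must be finite")
    return params.k * params.m * params.n * math.exp(
        -params.lambda_ * raw_score
    )


def bit_score(raw_score: float, lambda_: float, k: float) -> float:
    """Scale-free bit score (lambda * S - ln K) / ln 2."""
    return (lambda_ * raw_score - math.log(k)) / math.log(2.0)
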