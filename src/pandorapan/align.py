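"""Local pairwise alignment kernel.

Smith–Waterman with affine gaps, used by the greedy clusterer, the
best-reciprocal-hit search, AAI estimation, and the MITE scanner. Protein
alignments use BLOSUM62 with gap open 11 / extend 1; nucleotide alignments
use match +2 / mismatch −3 with gap open 5 / extend 2 (BLASTN-style
parameters). A contiguous gap of length g costs open + g·extend (NCBI
convention: the first gap column is charged open + extend).

The dynamic program is exact (no heuristic seeding or banding) and
deterministic: among equal-scoring traceback moves the order of preference
is diagonal > up > left, and the reported optimum is the first-encountered
maximal cell in row-major order.

Identity conventions, made explicit because downstream thresholds depend on
them:

- ``identity_short`` = identical columns / length of the shorter sequence
  (the CD-HIT convention used by the clustering thresholds);
- ``identity_columns`` = identical columns / alignment columns including
  gaps (the BLAST-style convention used for AAI and tabular hits).

E-values from this module are Karlin–Altschul approximations with ungapped
constants; they are meant for filtering alignments on synthetic data, not
for reproducing BLAST output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from pandorapan.utils import reverse_complement

# --- scoring tables ---------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
PROTEIN_ALPHABET = str(_BLOSUM62.alphabet)
_P_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}
_P_X = _P_INDEX["X"]
PROTEIN_MATRIX = np.ascontiguousarray(np.array(_BLOSUM62, dtype=np.int32))

NUC_ALPHABET = "ACGTN"
_N_INDEX = {c: i for i, c in enumerate(NUC_ALPHABET)}


def _nuc_matrix(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), -abs(mismatch), dtype=np.int32)
    for i in range(4):
        m[i, i] = match
    # N never counts as a match (also blocks alignment through masked runs)
    m[4, :] = -abs(mismatch)
    m[:, 4] = -abs(mismatch)
    return np.ascontiguousarray(m)


NUC_MATRIX = _nuc_matrix(2, 3)

# --- Karlin-Altschul constants ----------------------------------------------

# published ungapped BLOSUM62 parameters
_LAMBDA_PROTEIN = 0.3176
_K_PROTEIN = 0.134
# BLASTN-published K for reward/penalty 2/-3; lambda solved below from the
# identity sum(p_i p_j exp(lambda*s_ij)) = 1 at uniform base frequencies
_K_NUC = 0.41


def _solve_nuc_lambda(match: int = 2, mismatch: int = -3) -> float:
    def f(lam: float) -> float:
        return (4 * math.exp(lam * match) + 12 * math.exp(lam * mismatch)) / 16 - 1

    return float(brentq(f, 1e-6, 5.0))


_LAMBDA_NUC = _solve_nuc_lambda()


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string as indices into the BLOSUM62 matrix."""
    return np.array([_P_INDEX.get(c, _P_X) for c in seq.upper()], dtype=np.int64)


def encode_nucleotide(seq: str) -> np.ndarray:
    return np.array([_N_INDEX.get(c, 4) for c in seq.upper()], dtype=np.int64)


# --- kernel -----------------------------------------------------------------


@njit(cache=True, boundscheck=False)
def _sw_kernel(a, b, sub, gap_open, gap_ext):  # pragma: no cover - jitted
    """Affine-gap local alignment; returns score, identities, columns, spans.

    Traceback bits per cell: bits 0-1 = source of H (0 diag, 1 up/F,
    2 left/E, 3 restart), bit 2 = E extends E, bit 3 = F extends F.
    """
    m, n = a.shape[0], b.shape[0]
    NEG = np.int32(-(10 ** 8))
    oe = np.int32(gap_open + gap_ext)
    ge = np.int32(gap_ext)
    H0 = np.zeros(n + 1, dtype=np.int32)
    Fcol = np.full(n + 1, NEG, dtype=np.int32)
    tb = np.zeros((m + 1) * (n + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        row = sub[ai]
        base = i * (n + 1)
        hdiag = H0[0]
        hleft = np.int32(0)
        e = NEG
        for j in range(1, n + 1):
            t = np.uint8(0)
            e_open = hleft - oe
            e_ext = e - ge
            if e_open >= e_ext:
                e = e_open
            else:
                e = e_ext
                t = np.uint8(4)
            hup = H0[j]
            f_open = hup - oe
            f_ext = Fcol[j] - ge
            if f_open >= f_ext:
                f = f_open
            else:
                f = f_ext
                t += np.uint8(8)
            Fcol[j] = f
            h = hdiag + row[b[j - 1]]
            src = np.uint8(0)
            if f > h:
                h = f
                src = np.uint8(1)
            if e > h:
                h = e
                src = np.uint8(2)
            if h <= 0:
                h = np.int32(0)
                src = np.uint8(3)
            tb[base + j] = t + src
            hdiag = hup
            H0[j] = h
            hleft = h
            if h > best:
                best = h
                bi = i
                bj = j
        H0[0] = 0
    # traceback from the best cell; states: 0 = H, 1 = F (up), 2 = E (left)
    n_id = 0
    cols = 0
    i = bi
    j = bj
    state = 0
    while i > 0 and j > 0:
        t = tb[i * (n + 1) + j]
        if state == 0:
            src = t & 3
            if src == 3:
                break
            if src == 0:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    n_id += 1
                i -= 1
                j -= 1
            elif src == 1:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in b: consume a[i-1]
            cols += 1
            ext = t & 8
            i -= 1
            if not ext:
                state = 0
        else:  # gap in a: consume b[j-1]
            cols += 1
            ext = t & 4
            j -= 1
            if not ext:
                state = 0
    return best, n_id, cols, i, bi, j, bj


# --- result type ------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one local alignment.

    Spans are 0-based half-open on the original (forward) sequences. For a
    reverse-strand nucleotide match, ``s_span`` is reported on the forward
    subject and ``strand`` is '-'.
    """

    score: int
    n_identical: int
    aln_columns: int
    q_span: tuple[int, int]
    s_span: tuple[int, int]
    query_length: int
    subject_length: int
    kind: str = "protein"
    strand: str = "+"

    @property
    def identity_short(self) -> float:
        return self.n_identical / min(self.query_length, self.subject_length)

    @property
    def identity_columns(self) -> float:
        if self.aln_columns == 0:
            return 0.0
        return self.n_identical / self.aln_columns

    @property
    def coverage_query(self) -> float:
        return (self.q_span[1] - self.q_span[0]) / self.query_length

    @property
    def coverage_subject(self) -> float:
        return (self.s_span[1] - self.s_span[0]) / self.subject_length

    @property
    def coverage_shorter(self) -> float:
        """Aligned span of the shorter sequence over its length."""
        if self.query_length <= self.subject_length:
            return self.coverage_query
        return self.coverage_subject

    def evalue_approx(self, db_length: int | None = None) -> float:
        n = self.subject_length if db_length is None else db_length
        return evalue(self.score, self.query_length, n, kind=self.kind)


# --- public operations ------------------------------------------------------


def _align_encoded(
    ea: np.ndarray,
    eb: np.ndarray,
    sub: np.ndarray,
    gap_open: int,
    gap_ext: int,
    kind: str,
) -> AlignmentResult:
    score, n_id, cols, q0, q1, s0, s1 = _sw_kernel(ea, eb, sub, gap_open, gap_ext)
    if score <= 0:
        return AlignmentResult(0, 0, 0, (0, 0), (0, 0), len(ea), len(eb), kind)
    return AlignmentResult(
        int(score), int(n_id), int(cols), (q0, q1), (s0, s1), len(ea), len(eb), kind
    )


def align_protein(a: str, b: str, gap_open: int = 11, gap_ext: int = 1) -> AlignmentResult:
    """Smith–Waterman local alignment of two protein sequences (BLOSUM62)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _align_encoded(
        encode_protein(a), encode_protein(b), PROTEIN_MATRIX, gap_open, gap_ext, "protein"
    )


def align_nucleotide(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = 3,
    gap_open: int = 5,
    gap_ext: int = 2,
    rc_scan: bool = False,
) -> AlignmentResult:
    """Local alignment of two nucleotide sequences.

    With ``rc_scan`` the query is also aligned against the reverse complement
    of the subject and the better-scoring strand is returned, with subject
    coordinates mapped back to the forward strand.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    sub = NUC_MATRIX if (match, mismatch) == (2, 3) else _nuc_matrix(match, mismatch)
    ea = encode_nucleotide(a)
    eb = encode_nucleotide(b)
    fwd = _align_encoded(ea, eb, sub, gap_open, gap_ext, "nucleotide")
    if not rc_scan:
        return fwd
    erc = encode_nucleotide(reverse_complement(b))
    rev = _align_encoded(ea, erc, sub, gap_open, gap_ext, "nucleotide")
    if rev.score > fwd.score:
        n = len(b)
        s0, s1 = rev.s_span
        return AlignmentResult(
            rev.score,
            rev.n_identical,
            rev.aln_columns,
            rev.q_span,
            (n - s1, n - s0),
            rev.query_length,
            n,
            "nucleotide",
            strand="-",
        )
    return fwd


def evalue(score: float, m: int, n: int, kind: str = "protein") -> float:
    """Karlin–Altschul e-value approximation E = K·m·n·exp(−λS).

    Uses published ungapped constants (BLOSUM62 for protein; match +2 /
    mismatch −3 for nucleotide). Monotonically decreasing in ``score`` and
    linear in both sequence/database lengths.
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if kind == "protein":
        lam, k = _LAMBDA_PROTEIN, _K_PROTEIN
    elif kind == "nucleotide":
        lam, k = _LAMBDA_NUC, _K_NUC
    else:
        raise ValueError(f"unknown alignment kind {kind!r}")
    return k * m * n * math.exp(-lam * score)
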