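"""Independent pure-Python Smith-Waterman oracle for testing the kernel.

Implements the same affine-gap local alignment recurrence and the same
deterministic conventions as ``pandorapan.align._sw_kernel`` (gap cost
open + g*extend, tie preference diagonal > up > left, first-encountered
maximal cell in row-major order), but with a straightforward full-matrix
formulation so the two implementations share no code.
"""

from __future__ import annotations

NEG = -(10**8)


def sw_reference(a, b, sub, gap_open, gap_ext):
    """Local alignment of encoded sequences; returns the kernel's 7-tuple.

    ``a``/``b`` are integer index sequences, ``sub`` a substitution matrix
    (anything supporting sub[i][j]). Returns
    (score, n_identical, aln_columns, q0, q1, s0, s1).
    """
    m, n = len(a), len(b)
    oe = gap_open + gap_ext
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    # per-cell choices for the traceback
    h_src = [[3] * (n + 1) for _ in range(m + 1)]  # 0 diag, 1 up(F), 2 left(E), 3 stop
    e_ext = [[False] * (n + 1) for _ in range(m + 1)]
    f_ext = [[False] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i][j - 1] - oe
            e_from_e = E[i][j - 1] - gap_ext
            if e_open >= e_from_e:
                E[i][j] = e_open
            else:
                E[i][j] = e_from_e
                e_ext[i][j] = True
            f_open = H[i - 1][j] - oe
            f_from_f = F[i - 1][j] - gap_ext
            if f_open >= f_from_f:
                F[i][j] = f_open
            else:
                F[i][j] = f_from_f
                f_ext[i][j] = True
            h = H[i - 1][j - 1] + int(sub[a[i - 1]][b[j - 1]])
            src = 0
            if F[i][j] > h:
                h, src = F[i][j], 1
            if E[i][j] > h:
                h, src = E[i][j], 2
            if h <= 0:
                h, src = 0, 3
            H[i][j] = h
            h_src[i][j] = src
            if h > best:
                best, bi, bj = h, i, j
    # traceback (states: 0 in H, 1 in F, 2 in E)
    n_id = cols = 0
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        if state == 0:
            src = h_src[i][j]
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
        elif state == 1:
            cols += 1
            ext = f_ext[i][j]
            i -= 1
            if not ext:
                state = 0
        else:
            cols += 1
            ext = e_ext[i][j]
            j -= 1
            if not ext:
                state = 0
    return best, n_id, cols, i, bi, j, bj
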