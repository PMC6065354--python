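"""Numba kernels for read alignment and pileup accumulation.

Kept free of any I/O or object handling so the jitted code stays simple:
sequences arrive as small integer code arrays (A=0, C=1, G=2, T=3, N=4 in
reads / 5 in references so N never counts as a match).
"""

from __future__ import annotations

import numpy as np
from numba import njit

OP_M = 0  # match or mismatch: consumes read and ref
OP_I = 1  # insertion: consumes read only
OP_D = 2  # deletion: consumes ref only


@njit(cache=True)
def dp_align(read, ref, mismatch_cost, ins_cost, del_cost):
    """Minimum-cost semi-global alignment of ``read`` to ``ref``.

    The read is aligned end-to-end; leading and trailing reference bases are
    free (the read may match an internal span of the reference). Returns
    ``(cost, ref_start, n_steps, ops, n_match)`` where ``ops[:n_steps]`` is
    the per-column op code sequence in alignment order.

    Ties are resolved deterministically: the minimum-cost end column with the
    smallest reference coordinate, and during traceback match/mismatch is
    preferred over a gap, then deletion over insertion.
    """
    m = read.shape[0]
    n = ref.shape[0]
    D = np.empty((m + 1, n + 1), np.int32)
    for j in range(n + 1):
        D[0, j] = 0
    for i in range(1, m + 1):
        D[i, 0] = D[i - 1, 0] + ins_cost
        ri = read[i - 1]
        for j in range(1, n + 1):
            s = D[i - 1, j - 1]
            if ri != ref[j - 1]:
                s += mismatch_cost
            v = D[i - 1, j] + ins_cost
            if v < s:
                s = v
            v = D[i, j - 1] + del_cost
            if v < s:
                s = v
            D[i, j] = s

    cost = D[m, 0]
    j_end = 0
    for j in range(1, n + 1):
        if D[m, j] < cost:
            cost = D[m, j]
            j_end = j

    ops = np.empty(m + n, np.int8)
    k = m + n  # fill backwards
    n_match = 0
    i = m
    j = j_end
    while i > 0:
        cur = D[i, j]
        if j > 0:
            s = D[i - 1, j - 1]
            hit = read[i - 1] == ref[j - 1]
            if not hit:
                s += mismatch_cost
            if cur == s:
                k -= 1
                ops[k] = OP_M
                if hit:
                    n_match += 1
                i -= 1
                j -= 1
                continue
            if cur == D[i, j - 1] + del_cost:
                k -= 1
                ops[k] = OP_D
                j -= 1
                continue
        k -= 1
        ops[k] = OP_I
        i -= 1
    return cost, j, m + n - k, ops[k:], n_match


@njit(cache=True)
def accumulate_pileup(
    ref_len,
    mate_frag,
    mate_start,
    read_flat,
    read_off,
    ops_flat,
    ops_off,
    counts,
    frag_indel,
    indel_w0,
    indel_w1,
):
    """Accumulate per-position base/deletion counts from aligned mates.

    Mates must be sorted by (fragment index, mate rank); within a fragment
    the first mate seen wins wherever both mates cover a position, so each
    fragment contributes at most one observation per reference position.
    ``counts`` is (ref_len, 5): columns A, C, G, T, deletion. ``frag_indel``
    is set when any mate of the fragment carries an insertion or deletion op
    overlapping [indel_w0, indel_w1).
    """
    scratch = np.full(ref_len, -1, np.int8)
    touched = np.empty(ref_len, np.int64)
    nm = mate_frag.shape[0]
    idx = 0
    while idx < nm:
        f = mate_frag[idx]
        nt = 0
        while idx < nm and mate_frag[idx] == f:
            pos = mate_start[idx]
            rpos = read_off[idx]
            for t in range(ops_off[idx], ops_off[idx + 1]):
                op = ops_flat[2 * t]
                ln = ops_flat[2 * t + 1]
                if op == OP_M:
                    for _ in range(ln):
                        b = read_flat[rpos]
                        if b <= 3 and scratch[pos] == -1:
                            scratch[pos] = b
                            touched[nt] = pos
                            nt += 1
                        pos += 1
                        rpos += 1
                elif op == OP_I:
                    if indel_w0 <= pos <= indel_w1:
                        frag_indel[f] = True
                    rpos += ln
                else:  # OP_D
                    if pos < indel_w1 and pos + ln > indel_w0:
                        frag_indel[f] = True
                    for _ in range(ln):
                        if scratch[pos] == -1:
                            scratch[pos] = 4
                            touched[nt] = pos
                            nt += 1
                        pos += 1
            idx += 1
        for t in range(nt):
            p = touched[t]
            counts[p, scratch[p]] += 1
            scratch[p] = -1
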