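"""Dynamic-programming kernels for local profile alignment (numba-compiled).

State layout follows the classic profile architecture: per match column k
there are match (M_k), insert (I_k) and delete (D_k) states.  Alignments are
local on both the profile and the target: a path enters at any match state at
any target position for free, and exits from any match state for free.
Inserts emit at background frequency (log-odds 0); deletes emit nothing.

Scores are in nats; the caller converts to bits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def viterbi(em, x, tMM, tMI, tMD, tII, tIM, tDD, tDM):  # pragma: no cover - numba
    """Best local path score and its target envelope.

    Parameters
    ----------
    em : float64[M, A] match-emission log-odds (column A-1 is the wildcard, 0.0)
    x  : int64[L] encoded target

    Returns ``(score_nats, start, end)`` with 0-based inclusive target
    positions of the first/last residue consumed by the best path, or
    ``(NEG, -1, -1)`` for an empty target.
    """
    M = em.shape[0]
    L = x.shape[0]
    best = NEG
    best_start = -1
    best_end = -1
    vM_prev = np.full(M, NEG)
    vI_prev = np.full(M, NEG)
    vD_prev = np.full(M, NEG)
    sM_prev = np.full(M, -1, dtype=np.int64)
    sI_prev = np.full(M, -1, dtype=np.int64)
    sD_prev = np.full(M, -1, dtype=np.int64)
    vM = np.empty(M)
    vI = np.empty(M)
    vD = np.empty(M)
    sM = np.empty(M, dtype=np.int64)
    sI = np.empty(M, dtype=np.int64)
    sD = np.empty(M, dtype=np.int64)
    for i in range(L):
        xi = x[i]
        for k in range(M):
            # match: free entry, or continue from M/I/D at the previous column
            b = 0.0
            s = i
            if k > 0:
                c = vM_prev[k - 1] + tMM
                if c > b:
                    b = c
                    s = sM_prev[k - 1]
                c = vI_prev[k - 1] + tIM
                if c > b:
                    b = c
                    s = sI_prev[k - 1]
                c = vD_prev[k - 1] + tDM
                if c > b:
                    b = c
                    s = sD_prev[k - 1]
            vM[k] = em[k, xi] + b
            sM[k] = s
            # insert: stays at column k, emits at background (log-odds 0)
            bi = NEG
            si = -1
            if i > 0:
                c = vM_prev[k] + tMI
                if c > bi:
                    bi = c
                    si = sM_prev[k]
                c = vI_prev[k] + tII
                if c > bi:
                    bi = c
                    si = sI_prev[k]
            vI[k] = bi
            sI[k] = si
            # delete: consumes a column, no residue (same row, ascending k)
            bd = NEG
            sd = -1
            if k > 0:
                c = vM[k - 1] + tMD
                if c > bd:
                    bd = c
                    sd = sM[k - 1]
                c = vD[k - 1] + tDD
                if c > bd:
                    bd = c
                    sd = sD[k - 1]
            vD[k] = bd
            sD[k] = sd
            # free exit from any match state
            if vM[k] > best:
                best = vM[k]
                best_start = sM[k]
                best_end = i
        vM_prev, vM = vM, vM_prev
        vI_prev, vI = vI, vI_prev
        vD_prev, vD = vD, vD_prev
        sM_prev, sM = sM, sM_prev
        sI_prev, sI = sI, sI_prev
        sD_prev, sD = sD, sD_prev
    return best, best_start, best_end


@njit(cache=True)
def forward(em, x, tMM, tMI, tMD, tII, tIM, tDD, tDM):  # pragma: no cover - numba
    """Log-sum over all local paths (same path set as :func:`viterbi`), nats."""
    M = em.shape[0]
    L = x.shape[0]
    total = NEG
    fM_prev = np.full(M, NEG)
    fI_prev = np.full(M, NEG)
    fD_prev = np.full(M, NEG)
    fM = np.empty(M)
    fI = np.empty(M)
    fD = np.empty(M)
    for i in range(L):
        xi = x[i]
        for k in range(M):
            acc = 0.0  # free entry path
            if k > 0:
                acc = np.logaddexp(acc, fM_prev[k - 1] + tMM)
                acc = np.logaddexp(acc, fI_prev[k - 1] + tIM)
                acc = np.logaddexp(acc, fD_prev[k - 1] + tDM)
            fM[k] = em[k, xi] + acc
            if i > 0:
                fI[k] = np.logaddexp(fM_prev[k] + tMI, fI_prev[k] + tII)
            else:
                fI[k] = NEG
            if k > 0:
                fD[k] = np.logaddexp(fM[k - 1] + tMD, fD[k - 1] + tDD)
            else:
                fD[k] = NEG
            total = np.logaddexp(total, fM[k])
        fM_prev, fM = fM, fM_prev
        fI_prev, fI = fI, fI_prev
        fD_prev, fD = fD, fD_prev
    return total
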