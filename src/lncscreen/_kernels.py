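"""Numba inner loops: folding DP, duplex DP, Needleman-Wunsch alignment.

All kernels operate on integer-encoded sequences / precomputed pair-weight
matrices so the same DP serves single sequences and alignment-column
consensus scoring.  Python wrappers live in :mod:`lncscreen.thermo` and
:mod:`lncscreen.candidate_discovery`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e18


@njit(cache=True)
def fold_dp(W: np.ndarray, hp_base: float, hp_per: float, min_hp: int,
            bulge_base: float, bulge_per: float, int_base: float,
            int_per: float, max_loop: int):
    """Minimum-energy nested structure DP over a pair-weight matrix.

    W[i, j] > 0 means positions i < j may pair with weight W[i, j]; a stack of
    (i,j) on (k,l) scores -(W[i,j]+W[k,l])/2.  Returns (V, M) where V[i,j] is
    the best energy given (i,j) paired and M[i,j] the best energy of [i..j]
    containing at least one pair.  Unpaired bases are free; multibranch loops
    carry no closing term.
    """
    n = W.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            if W[i, j] > 0.0:
                best = INF
                u = j - i - 1
                if u >= min_hp:
                    best = hp_base + hp_per * (u - min_hp)
                for k in range(i + 1, j):
                    d1 = k - i - 1
                    if d1 > max_loop:
                        break
                    for l in range(j - 1, k, -1):
                        d2 = j - l - 1
                        if d1 + d2 > max_loop:
                            break
                        if W[k, l] <= 0.0 or V[k, l] >= INF / 2:
                            continue
                        if d1 == 0 and d2 == 0:
                            e = V[k, l] - 0.5 * (W[i, j] + W[k, l])
                        elif d1 == 0 or d2 == 0:
                            e = V[k, l] + bulge_base + bulge_per * (d1 + d2)
                        else:
                            e = V[k, l] + int_base + int_per * (d1 + d2)
                        if e < best:
                            best = e
                for m in range(i + 2, j - 1):
                    if M[i + 1, m] < INF / 2 and M[m + 1, j - 1] < INF / 2:
                        e = M[i + 1, m] + M[m + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # M: at least one pair inside [i..j]
            bm = INF
            if i + 1 <= j:
                bm = M[i + 1, j]
            for k in range(i + 1, j + 1):
                if W[i, k] > 0.0 and V[i, k] < INF / 2:
                    rest = 0.0
                    if k + 1 <= j and M[k + 1, j] < 0.0:
                        rest = M[k + 1, j]
                    e = V[i, k] + rest
                    if e < bm:
                        bm = e
            M[i, j] = bm
    return V, M


@njit(cache=True)
def duplex_dp(W: np.ndarray, bulge_base: float, bulge_per: float,
              int_base: float, int_per: float, max_loop: int):
    """Best intermolecular duplex energy over pairable (i, j) of two molecules.

    W[i, j] > 0 marks a possible pair between position i of molecule A and j
    of molecule B; the duplex is antiparallel, so successive pairs move right
    in A and left in B.  D[i, j] is the best energy of a duplex whose last
    pair is (i, j); a lone pair scores 0.
    """
    n, m = W.shape
    D = np.full((n, m), INF)
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if W[i, j] <= 0.0:
                continue
            best = 0.0
            for ip in range(i - 1, max(-1, i - 2 - max_loop), -1):
                d1 = i - ip - 1
                for jp in range(j + 1, min(m, j + 2 + max_loop)):
                    d2 = jp - j - 1
                    if d1 + d2 > max_loop:
                        break
                    if W[ip, jp] <= 0.0 or D[ip, jp] >= INF / 2:
                        continue
                    if d1 == 0 and d2 == 0:
                        e = D[ip, jp] - 0.5 * (W[ip, jp] + W[i, j])
                    elif d1 == 0 or d2 == 0:
                        e = D[ip, jp] + bulge_base + bulge_per * (d1 + d2)
                    else:
                        e = D[ip, jp] + int_base + int_per * (d1 + d2)
                    if e < best:
                        best = e
            D[i, j] = best
    return D


@njit(cache=True)
def nw_align(x: np.ndarray, y: np.ndarray, match: float, mismatch: float,
             gap: float):
    """Global alignment (linear gap cost); returns (score, pointer matrix).

    Pointers: 0 diagonal, 1 up (gap in y), 2 left (gap in x).
    """
    n, m = len(x), len(y)
    S = np.empty((n + 1, m + 1), dtype=np.float32)
    P = np.zeros((n + 1, m + 1), dtype=np.int8)
    S[0, 0] = 0.0
    for i in range(1, n + 1):
        S[i, 0] = gap * i
        P[i, 0] = 1
    for j in range(1, m + 1):
        S[0, j] = gap * j
        P[0, j] = 2
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            s = match if xi == y[j - 1] else mismatch
            d = S[i - 1, j - 1] + s
            u = S[i - 1, j] + gap
            l = S[i, j - 1] + gap
            if d >= u and d >= l:
                S[i, j] = d
                P[i, j] = 0
            elif u >= l:
                S[i, j] = u
                P[i, j] = 1
            else:
                S[i, j] = l
                P[i, j] = 2
    return S[n, m], P
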