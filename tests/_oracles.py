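"""Independent brute-force oracles used by the test suite.

These are deliberately written against the *model definition* (loop
decomposition scoring, per-base bitmaps, sliding-window scans), not against
the package's dynamic programs, so they can certify the implementations.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from lncscreen.thermo import EnergyParams, encode

INF = float("inf")


# ---------------------------------------------------------------------------
# folding: enumerate all nested structures and score by loop decomposition

def enumerate_fold_mfe(seq: str, params: EnergyParams) -> float:
    """Exhaustive minimum energy over all nested structures (n <= ~14)."""
    enc = encode(seq)
    n = len(enc)
    W = params.pair_table[enc[:, None], enc[None, :]]

    @lru_cache(maxsize=None)
    def structs(i: int, j: int):
        if i >= j:
            return [()]
        out = list(structs(i + 1, j))
        for k in range(i + 1, j + 1):
            if W[i, k] > 0:
                for left in structs(i + 1, k - 1):
                    for right in structs(k + 1, j):
                        out.append(((i, k),) + left + right)
        return out

    best = 0.0
    for pairs in structs(0, n - 1):
        e = score_structure(pairs, W, params)
        if e < best:
            best = e
    structs.cache_clear()
    return best


def score_structure(pairs, W, params: EnergyParams) -> float:
    """Loop-decomposition energy of one nested structure (inf if disallowed)."""
    if not pairs:
        return 0.0
    ps = sorted(pairs)
    total = 0.0
    for (i, j) in ps:
        children = [
            (k, l) for (k, l) in ps
            if i < k and l < j and not any(
                i < a and b < j and a < k and l < b for (a, b) in ps)
        ]
        if len(children) == 0:
            u = j - i - 1
            if u < params.min_hairpin_loop:
                return INF
            total += params.hairpin_base + params.hairpin_per_nt * (
                u - params.min_hairpin_loop)
        elif len(children) == 1:
            (k, l) = children[0]
            d1, d2 = k - i - 1, j - l - 1
            if d1 + d2 == 0:
                total += -0.5 * (W[i, j] + W[k, l])
            elif d1 + d2 > params.max_interior_unpaired:
                return INF
            elif d1 == 0 or d2 == 0:
                total += params.bulge_base + params.bulge_per_nt * (d1 + d2)
            else:
                total += params.internal_base + params.internal_per_nt * (d1 + d2)
        # multibranch closings contribute nothing
    return total


# ---------------------------------------------------------------------------
# duplex: enumerate all antiparallel non-crossing intermolecular pairings

def enumerate_duplex_mfe(seq_a: str, seq_b: str, params: EnergyParams) -> float:
    ea, eb = encode(seq_a), encode(seq_b)
    W = params.pair_table[ea[:, None], eb[None, :]]
    n, m = W.shape
    best = [0.0]

    def score(chain) -> float:
        total = 0.0
        for t in range(1, len(chain)):
            i0, j0 = chain[t - 1]
            i1, j1 = chain[t]
            d1, d2 = i1 - i0 - 1, j0 - j1 - 1
            if d1 + d2 == 0:
                total += -0.5 * (W[i0, j0] + W[i1, j1])
            elif d1 + d2 > params.max_interior_unpaired:
                return INF
            elif d1 == 0 or d2 == 0:
                total += params.bulge_base + params.bulge_per_nt * (d1 + d2)
            else:
                total += params.internal_base + params.internal_per_nt * (d1 + d2)
        return total

    def extend(chain):
        e = score(chain)
        if e < best[0]:
            best[0] = e
        last_i, last_j = chain[-1] if chain else (-1, m)
        for i in range(last_i + 1, n):
            for j in range(last_j - 1, -1, -1):
                if W[i, j] > 0:
                    extend(chain + [(i, j)])

    extend([])
    return best[0]


# ---------------------------------------------------------------------------
# intervals: per-base bitmap over a toy chromosome

def bitmap(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[iv.start:iv.end] = True
    return mask


def bitmap_to_intervals(mask: np.ndarray, seqid: str = "chr1"):
    from lncscreen.genome_io import GenomicInterval

    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append(GenomicInterval(seqid, start, i))
            in_run = False
    if in_run:
        out.append(GenomicInterval(seqid, start, len(mask)))
    return out


# ---------------------------------------------------------------------------
# mimicry: brute-force sliding window with the same mismatch weights

def brute_force_sites(host: str, mirna: str, max_mismatch: float,
                      gu_half: bool = True) -> list[int]:
    """Offsets (+ orientation only) where the miRNA binds within the cap."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    host = host.upper().replace("T", "U")
    mirna = mirna.upper().replace("T", "U")
    m = len(mirna)
    hits = []
    for off in range(len(host) - m + 1):
        w = host[off:off + m]
        total = 0.0
        for t in range(m):
            h, mb = w[t], mirna[m - 1 - t]
            if comp.get(h) == mb:
                continue
            if gu_half and (h, mb) in {("G", "U"), ("U", "G")}:
                total += 0.5
            else:
                total += 1.0
        if np.floor(total + 0.5) <= max_mismatch:
            hits.append(off)
    return hits


# ---------------------------------------------------------------------------
# enrichment: exact enumeration of the hypergeometric tail for small N

def exact_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    from math import comb

    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += comb(K, x) * comb(N - K, n - x)
    return acc / total
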