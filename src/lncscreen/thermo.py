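"""Simplified nearest-neighbor RNA thermodynamics.

The model, shared by single-sequence folding, alignment consensus folding and
intermolecular duplex prediction, is a stacking model:

* every Watson-Crick or G.U pair has a positive weight ``w`` (versioned table
  ``data/energy_params.json``); a stack of pair p_out on p_in contributes
  ``-(w(p_out) + w(p_in)) / 2`` kcal/mol, so an h-pair helix scores the sum of
  its h-1 stack terms;
* hairpin loops (minimum 3 unpaired) and bulge/internal loops carry linear
  size penalties; interior loops with more than ``max_interior_unpaired``
  unpaired bases are disallowed;
* unpaired bases and multibranch closings are free.

This is deliberately far simpler than the Turner rules: it is a reproducible,
exhaustively testable stand-in whose minimum is found by an O(n^3) interval
DP, and every downstream score (z-score, SCI, duplex energy) uses the same
parameter table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from numba import njit as _njit

from ._kernels import INF, duplex_dp, fold_dp

__all__ = [
    "EnergyParams",
    "load_params",
    "fold_mfe",
    "fold_energy",
    "consensus_fold",
    "duplex_mfe",
    "dinucleotide_shuffle",
    "encode",
]

_EPS = 1e-6
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4,
               "a": 0, "c": 1, "g": 2, "u": 3, "t": 3, "n": 4}


@dataclass(frozen=True)
class EnergyParams:
    version: str
    pair_table: np.ndarray          # 5x5 pair weights, 0 = cannot pair
    hairpin_base: float
    hairpin_per_nt: float
    min_hairpin_loop: int
    bulge_base: float
    bulge_per_nt: float
    internal_base: float
    internal_per_nt: float
    max_interior_unpaired: int
    consensus_covariation_bonus: float
    consensus_nonpair_penalty: float


@lru_cache(maxsize=1)
def load_params() -> EnergyParams:
    """Load the packaged energy parameter table."""
    raw = json.loads(
        resources.files("lncscreen").joinpath("data/energy_params.json").read_text()
    )
    table = np.zeros((5, 5))
    for pair, w in raw["pair_weights"].items():
        i, j = _BASE_INDEX[pair[0]], _BASE_INDEX[pair[1]]
        table[i, j] = w
    return EnergyParams(
        version=raw["version"],
        pair_table=table,
        hairpin_base=raw["hairpin_base"],
        hairpin_per_nt=raw["hairpin_per_nt"],
        min_hairpin_loop=raw["min_hairpin_loop"],
        bulge_base=raw["bulge_base"],
        bulge_per_nt=raw["bulge_per_nt"],
        internal_base=raw["internal_base"],
        internal_per_nt=raw["internal_per_nt"],
        max_interior_unpaired=raw["max_interior_unpaired"],
        consensus_covariation_bonus=raw["consensus_covariation_bonus"],
        consensus_nonpair_penalty=raw["consensus_nonpair_penalty"],
    )


def encode(sequence: str) -> np.ndarray:
    """Encode an RNA/DNA string as ints (A=0 C=1 G=2 U/T=3 N=4).

    Raises ``ValueError`` on symbols outside the A/C/G/T/U/N alphabet.
    """
    try:
        return np.array([_BASE_INDEX[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide symbol {exc.args[0]!r} in sequence") from exc


def _pair_weight_matrix(enc: np.ndarray, params: EnergyParams) -> np.ndarray:
    return params.pair_table[enc[:, None], enc[None, :]]


def _run_fold(W: np.ndarray, params: EnergyParams):
    return fold_dp(
        np.ascontiguousarray(W, dtype=np.float64),
        params.hairpin_base, params.hairpin_per_nt, params.min_hairpin_loop,
        params.bulge_base, params.bulge_per_nt,
        params.internal_base, params.internal_per_nt,
        params.max_interior_unpaired,
    )


def _traceback(W: np.ndarray, V: np.ndarray, M: np.ndarray,
               params: EnergyParams) -> list[tuple[int, int]]:
    """Recover one optimal pair set from the filled DP matrices."""
    n = W.shape[0]
    pairs: list[tuple[int, int]] = []
    if n < 2 or M[0, n - 1] >= 0.0:
        return pairs
    stack: list[tuple[str, int, int]] = [("M", 0, n - 1)]
    while stack:
        which, i, j = stack.pop()
        if which == "M":
            target = M[i, j]
            if i + 1 <= j and abs(M[i + 1, j] - target) < _EPS:
                stack.append(("M", i + 1, j))
                continue
            found = False
            for k in range(i + 1, j + 1):
                if W[i, k] <= 0.0 or V[i, k] >= INF / 2:
                    continue
                rest = 0.0
                if k + 1 <= j and M[k + 1, j] < 0.0:
                    rest = M[k + 1, j]
                if abs(V[i, k] + rest - target) < _EPS:
                    pairs.append((i, k))
                    stack.append(("V", i, k))
                    if rest < 0.0:
                        stack.append(("M", k + 1, j))
                    found = True
                    break
            if not found:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in M")
        else:  # V, (i, j) already recorded as a pair
            target = V[i, j]
            u = j - i - 1
            if u >= params.min_hairpin_loop and abs(
                    params.hairpin_base
                    + params.hairpin_per_nt * (u - params.min_hairpin_loop)
                    - target) < _EPS:
                continue
            found = False
            for k in range(i + 1, j):
                d1 = k - i - 1
                if d1 > params.max_interior_unpaired or found:
                    break
                for l in range(j - 1, k, -1):
                    d2 = j - l - 1
                    if d1 + d2 > params.max_interior_unpaired:
                        break
                    if W[k, l] <= 0.0 or V[k, l] >= INF / 2:
                        continue
                    if d1 == 0 and d2 == 0:
                        e = V[k, l] - 0.5 * (W[i, j] + W[k, l])
                    elif d1 == 0 or d2 == 0:
                        e = V[k, l] + params.bulge_base + params.bulge_per_nt * (d1 + d2)
                    else:
                        e = V[k, l] + params.internal_base + params.internal_per_nt * (d1 + d2)
                    if abs(e - target) < _EPS:
                        pairs.append((k, l))
                        stack.append(("V", k, l))
                        found = True
                        break
            if found:
                continue
            for m in range(i + 2, j - 1):
                if M[i + 1, m] < INF / 2 and M[m + 1, j - 1] < INF / 2 and abs(
                        M[i + 1, m] + M[m + 1, j - 1] - target) < _EPS:
                    stack.append(("M", i + 1, m))
                    stack.append(("M", m + 1, j - 1))
                    found = True
                    break
            if not found:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in V")
    return pairs


def _dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def fold_mfe(sequence: str, params: EnergyParams | None = None
             ) -> tuple[float, str]:
    """Minimum free energy and dot-bracket structure of one sequence.

    T is read as U.  Returns (0.0, all-dots) when no structure is stabilizing.
    """
    params = params or load_params()
    enc = encode(sequence)
    n = len(enc)
    if n < 2:
        return 0.0, "." * n
    W = _pair_weight_matrix(enc, params)
    V, M = _run_fold(W, params)
    energy = min(0.0, M[0, n - 1]) if M[0, n - 1] < INF / 2 else 0.0
    if energy >= 0.0:
        return 0.0, "." * n
    pairs = _traceback(W, V, M, params)
    return float(energy), _dotbracket(n, pairs)


def fold_energy(sequence_or_enc, params: EnergyParams | None = None) -> float:
    """Energy-only fold (no traceback); accepts a string or encoded array."""
    params = params or load_params()
    enc = (sequence_or_enc if isinstance(sequence_or_enc, np.ndarray)
           else encode(sequence_or_enc))
    n = len(enc)
    if n < 2:
        return 0.0
    W = _pair_weight_matrix(enc, params)
    _V, M = _run_fold(W, params)
    e = M[0, n - 1]
    return float(min(0.0, e)) if e < INF / 2 else 0.0


def consensus_pair_weights(rows: list[str], params: EnergyParams | None = None
                           ) -> np.ndarray:
    """Column-pair consensus weight matrix for an alignment.

    For columns (c1, c2): mean pair weight over rows able to pair, plus a
    covariation bonus per extra distinct pair type, minus a penalty times the
    fraction of rows unable to pair; clamped at 0 (unpairable).  All-gap
    columns must be stripped by the caller.
    """
    params = params or load_params()
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows have unequal gapped lengths")
    enc = np.array(
        [[_BASE_INDEX.get(c, -1) if c != "-" else -1 for c in row] for row in rows],
        dtype=np.int8,
    )
    return _cons_weights(
        enc, params.pair_table,
        params.consensus_covariation_bonus, params.consensus_nonpair_penalty)


@_njit(cache=True)
def _cons_weights(enc, table, bonus, penalty):
    nrow, n = enc.shape
    W = np.zeros((n, n))
    seen = np.zeros(25, dtype=np.uint8)
    for c1 in range(n):
        for c2 in range(c1 + 1, n):
            total = 0.0
            n_pairable = 0
            n_types = 0
            for t in range(25):
                seen[t] = 0
            for r in range(nrow):
                b1 = enc[r, c1]
                b2 = enc[r, c2]
                if b1 < 0 or b2 < 0:
                    continue
                w = table[b1, b2]
                if w > 0.0:
                    total += w
                    n_pairable += 1
                    t = 5 * b1 + b2
                    if seen[t] == 0:
                        seen[t] = 1
                        n_types += 1
            if n_pairable == 0:
                continue
            frac_unable = (nrow - n_pairable) / nrow
            what = total / nrow + bonus * (n_types - 1) - penalty * frac_unable
            if what > 0.0:
                W[c1, c2] = what
    return W


def consensus_fold(rows: list[str], params: EnergyParams | None = None
                   ) -> tuple[float, str]:
    """Consensus MFE and structure of an alignment (rows gapped, equal length).

    Identical rows reproduce the single-sequence fold exactly; compensatory
    substitutions at paired columns earn a covariation bonus while rows unable
    to pair are penalized.
    """
    params = params or load_params()
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows have unequal gapped lengths")
    # strip all-gap columns: they contribute nothing
    keep = [c for c in range(len(rows[0])) if any(r[c] != "-" for r in rows)]
    rows = ["".join(r[c] for c in keep) for r in rows]
    n = len(rows[0])
    if n < 2:
        return 0.0, "." * n
    W = consensus_pair_weights(rows, params)
    V, M = _run_fold(W, params)
    e = M[0, n - 1]
    if e >= INF / 2 or e >= 0.0:
        return 0.0, "." * n
    pairs = _traceback(W, V, M, params)
    return float(e), _dotbracket(n, pairs)


def duplex_mfe_pairs(seq_a: str, seq_b: str, params: EnergyParams | None = None
                     ) -> tuple[float, list[tuple[int, int]]]:
    """Optimal intermolecular duplex: energy and antiparallel pair list.

    Pairing is intermolecular only and non-crossing; (i, j) pairs position i
    of ``seq_a`` with position j of ``seq_b``.  No complementarity anywhere
    yields (0.0, []).
    """
    params = params or load_params()
    ea, eb = encode(seq_a), encode(seq_b)
    if len(ea) == 0 or len(eb) == 0:
        return 0.0, []
    W = params.pair_table[ea[:, None], eb[None, :]]
    D = duplex_dp(np.ascontiguousarray(W, dtype=np.float64),
                  params.bulge_base, params.bulge_per_nt,
                  params.internal_base, params.internal_per_nt,
                  params.max_interior_unpaired)
    masked = np.where(D < INF / 2, D, np.inf)
    if not np.isfinite(masked).any():
        return 0.0, []
    i, j = np.unravel_index(int(np.argmin(masked)), D.shape)
    best = masked[i, j]
    if best >= 0.0:
        return 0.0, []
    # traceback
    pairs = [(int(i), int(j))]
    while True:
        target = D[i, j]
        if abs(target) < _EPS:
            break
        found = False
        for ip in range(i - 1, max(-1, i - 2 - params.max_interior_unpaired), -1):
            d1 = i - ip - 1
            for jp in range(j + 1, min(len(eb), j + 2 + params.max_interior_unpaired)):
                d2 = jp - j - 1
                if d1 + d2 > params.max_interior_unpaired:
                    break
                if W[ip, jp] <= 0.0 or D[ip, jp] >= INF / 2:
                    continue
                if d1 == 0 and d2 == 0:
                    e = D[ip, jp] - 0.5 * (W[ip, jp] + W[i, j])
                elif d1 == 0 or d2 == 0:
                    e = D[ip, jp] + params.bulge_base + params.bulge_per_nt * (d1 + d2)
                else:
                    e = D[ip, jp] + params.internal_base + params.internal_per_nt * (d1 + d2)
                if abs(e - target) < _EPS:
                    pairs.append((ip, jp))
                    i, j = ip, jp
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - defensive
            raise RuntimeError("duplex traceback failed")
    pairs.sort()
    return float(best), pairs


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erickson Euler-walk method).

    Preserves the exact dinucleotide (and hence mononucleotide) composition.
    Sequences shorter than 4 nt are returned unchanged.
    """
    s = list(sequence)
    if len(s) < 4:
        return sequence
    last_char = s[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges)
    # choose terminal edges forming an arborescence into last_char
    for _ in range(10_000):
        terminal = {}
        for v in vertices:
            if v == last_char:
                continue
            terminal[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in terminal:
            seen = {v}
            cur = v
            while cur != last_char:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("shuffle arborescence search failed")
    walk_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in terminal:
            rest.remove(terminal[v])
        rng.shuffle(rest)
        if v in terminal:
            rest.append(terminal[v])
        walk_edges[v] = rest
    out = [s[0]]
    cur = s[0]
    pos = {v: 0 for v in vertices}
    for _ in range(len(s) - 1):
        nxt = walk_edges[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
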