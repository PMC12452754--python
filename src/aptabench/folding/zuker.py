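"""Minimum-free-energy secondary structure by Zuker-style dynamic programming.

Recursions over four tables (``V`` closed structures, ``M``/``M1`` multiloop
segments, ``F`` exterior loop) with interior loops capped at
``params.MAXLOOP`` unpaired nucleotides, hairpin loops of at least
``params.MIN_HAIRPIN``, an affine multiloop model and both-side dangles
(d2 convention).  Energies are integers in 0.01 kcal/mol; the fill kernels
are JIT-compiled with numba, the traceback re-derives decisions in Python
from the filled tables.

A structure is reported only when its energy is strictly negative; otherwise
the open chain (all dots, MFE 0) is returned, matching the convention that
MFE = 0 means "does not fold".
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import (
    BULGE_INIT,
    DANGLE3,
    DANGLE5,
    HAIRPIN_INIT,
    HAIRPIN_MM_BASE,
    INF,
    INT11_BASE,
    INT11_GG_BONUS,
    INTERNAL_AU_CLOSURE,
    INTERNAL_INIT,
    INTERNAL_MM_GA,
    INTERNAL_MM_UU,
    IS_AU_GU,
    MAXLOOP,
    MIN_HAIRPIN,
    ML_BRANCH,
    ML_CLOSING,
    MM_BONUS_GA,
    MM_BONUS_GG,
    MM_BONUS_UU,
    NINIO_MAX,
    NINIO_PER_NT,
    PAIR_TYPE,
    REVERSE_PAIR,
    STACK,
    TERMINAL_AU,
    encode,
)

__all__ = ["fold_mfe", "energies"]

_A, _C, _G, _U = 0, 1, 2, 3
_LOOP_MAX = 511


@njit(cache=True)
def _hairpin_mm_bonus(x: int, y: int) -> int:
    if (x == _G and y == _A) or (x == _A and y == _G):
        return MM_BONUS_GA
    if x == _U and y == _U:
        return MM_BONUS_UU
    if x == _G and y == _G:
        return MM_BONUS_GG
    return 0


@njit(cache=True)
def _internal_mm_bonus(x: int, y: int) -> int:
    if (x == _G and y == _A) or (x == _A and y == _G):
        return INTERNAL_MM_GA
    if x == _U and y == _U:
        return INTERNAL_MM_UU
    return 0


@njit(cache=True)
def e_hairpin(S: np.ndarray, i: int, j: int) -> int:
    """Hairpin loop closed by pair (i, j)."""
    size = j - i - 1
    pt = PAIR_TYPE[S[i], S[j]]
    idx = size if size < _LOOP_MAX else _LOOP_MAX
    e = HAIRPIN_INIT[idx] + TERMINAL_AU * IS_AU_GU[pt]
    if size >= 4:
        e += HAIRPIN_MM_BASE[pt] + _hairpin_mm_bonus(S[i + 1], S[j - 1])
    return e


@njit(cache=True)
def e_interior(S: np.ndarray, i: int, j: int, p: int, q: int) -> int:
    """Stack, bulge or internal loop between pairs (i, j) and (p, q)."""
    pt1 = PAIR_TYPE[S[i], S[j]]
    pt2 = PAIR_TYPE[S[p], S[q]]
    n1 = p - i - 1
    n2 = j - q - 1
    if n1 == 0 and n2 == 0:
        return STACK[pt1, pt2]
    if n1 == 0 or n2 == 0:
        size = n1 + n2
        if size == 1:
            # single-nucleotide bulge preserves helix stacking
            return BULGE_INIT[1] + STACK[pt1, pt2]
        idx = size if size < _LOOP_MAX else _LOOP_MAX
        return BULGE_INIT[idx] + TERMINAL_AU * (IS_AU_GU[pt1] + IS_AU_GU[pt2])
    closure = INTERNAL_AU_CLOSURE * (IS_AU_GU[pt1] + IS_AU_GU[pt2])
    if n1 == 1 and n2 == 1:
        e = INT11_BASE + closure
        if S[i + 1] == _G and S[j - 1] == _G:
            e += INT11_GG_BONUS
        return e
    size = n1 + n2
    asym = NINIO_PER_NT * (n1 - n2 if n1 > n2 else n2 - n1)
    if asym > NINIO_MAX:
        asym = NINIO_MAX
    idx = size if size < _LOOP_MAX else _LOOP_MAX
    e = INTERNAL_INIT[idx] + asym + closure
    if n1 > 1 and n2 > 1:
        e += _internal_mm_bonus(S[i + 1], S[j - 1])
        e += _internal_mm_bonus(S[q + 1], S[p - 1])
    return e


@njit(cache=True)
def e_ml_stem(pt: int, five: int, three: int) -> int:
    """Branch contribution of a helix inside a multiloop (d2 dangles)."""
    return ML_BRANCH + TERMINAL_AU * IS_AU_GU[pt] + DANGLE5[pt, five] + DANGLE3[pt, three]


@njit(cache=True)
def e_ext_stem(S: np.ndarray, i: int, j: int) -> int:
    """Contribution of a helix (i, j) in the exterior loop (d2 dangles)."""
    pt = PAIR_TYPE[S[i], S[j]]
    e = TERMINAL_AU * IS_AU_GU[pt]
    if i > 0:
        e += DANGLE5[pt, S[i - 1]]
    if j < len(S) - 1:
        e += DANGLE3[pt, S[j + 1]]
    return e


@njit(cache=True)
def _fill(S: np.ndarray):
    n = len(S)
    V = np.full((n, n), INF, dtype=np.int64)
    M = np.full((n, n), INF, dtype=np.int64)
    M1 = np.full((n, n), INF, dtype=np.int64)
    F = np.zeros(n + 1, dtype=np.int64)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            pt = PAIR_TYPE[S[i], S[j]]
            # --- V ---
            if pt > 0 and d > MIN_HAIRPIN:
                best = e_hairpin(S, i, j)
                p_hi = j - MIN_HAIRPIN - 2  # inner pair needs q >= p + MIN_HAIRPIN + 1
                if p_hi > i + MAXLOOP + 1:
                    p_hi = i + MAXLOOP + 1
                for p in range(i + 1, p_hi + 1):
                    n1 = p - i - 1
                    q_lo = j - 1 - (MAXLOOP - n1)
                    if q_lo < p + MIN_HAIRPIN + 1:
                        q_lo = p + MIN_HAIRPIN + 1
                    for q in range(q_lo, j):
                        if PAIR_TYPE[S[p], S[q]] > 0 and V[p, q] < INF:
                            e = e_interior(S, i, j, p, q) + V[p, q]
                            if e < best:
                                best = e
                # multiloop closing
                rpt = REVERSE_PAIR[pt]
                base = ML_CLOSING + e_ml_stem(rpt, S[j - 1], S[i + 1])
                for u in range(i + 2, j - 1):
                    if M[i + 1, u - 1] < INF and M1[u, j - 1] < INF:
                        e = base + M[i + 1, u - 1] + M1[u, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # --- M1: one stem starting exactly at i, trailing unpaired free ---
            m1 = M1[i, j - 1] if j - 1 > i else INF
            if pt > 0 and V[i, j] < INF and i > 0 and j < n - 1:
                e = V[i, j] + e_ml_stem(pt, S[i - 1], S[j + 1])
                if e < m1:
                    m1 = e
            M1[i, j] = m1
            # --- M: at least one stem anywhere in [i, j] ---
            m = M[i, j - 1] if j - 1 >= i else INF
            if M1[i, j] < m:
                m = M1[i, j]
            for u in range(i + 1, j + 1):
                if M[i, u - 1] < INF and M1[u, j] < INF:
                    e = M[i, u - 1] + M1[u, j]
                    if e < m:
                        m = e
            M[i, j] = m
    for jj in range(1, n + 1):
        j = jj - 1
        best = F[jj - 1]
        for i in range(0, j - MIN_HAIRPIN):
            if PAIR_TYPE[S[i], S[j]] > 0 and V[i, j] < INF:
                e = F[i] + V[i, j] + e_ext_stem(S, i, j)
                if e < best:
                    best = e
        F[jj] = best
    return V, M, M1, F


def _trace_V(S, V, M, M1, pairs, i, j):
    pairs[i] = j
    pairs[j] = i
    target = V[i, j]
    if target == e_hairpin(S, i, j):
        return
    p_hi = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 2)
    for p in range(i + 1, p_hi + 1):
        n1 = p - i - 1
        q_lo = max(p + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - n1))
        for q in range(q_lo, j):
            if PAIR_TYPE[S[p], S[q]] > 0 and V[p, q] < INF:
                if e_interior(S, i, j, p, q) + V[p, q] == target:
                    _trace_V(S, V, M, M1, pairs, p, q)
                    return
    rpt = REVERSE_PAIR[PAIR_TYPE[S[i], S[j]]]
    base = ML_CLOSING + e_ml_stem(rpt, S[j - 1], S[i + 1])
    for u in range(i + 2, j - 1):
        if M[i + 1, u - 1] < INF and M1[u, j - 1] < INF:
            if base + M[i + 1, u - 1] + M1[u, j - 1] == target:
                _trace_M(S, V, M, M1, pairs, i + 1, u - 1)
                _trace_M1(S, V, M, M1, pairs, u, j - 1)
                return
    raise AssertionError(f"traceback failed at V({i},{j})")


def _trace_M1(S, V, M, M1, pairs, i, j):
    while j - 1 > i and M1[i, j] == M1[i, j - 1]:
        j -= 1
    _trace_V(S, V, M, M1, pairs, i, j)


def _trace_M(S, V, M, M1, pairs, i, j):
    while True:
        if M[i, j] == M1[i, j]:
            _trace_M1(S, V, M, M1, pairs, i, j)
            return
        if j - 1 >= i and M[i, j] == M[i, j - 1]:
            j -= 1
            continue
        for u in range(i + 1, j + 1):
            if M[i, u - 1] < INF and M1[u, j] < INF and M[i, u - 1] + M1[u, j] == M[i, j]:
                _trace_M1(S, V, M, M1, pairs, u, j)
                j = u - 1
                break
        else:
            raise AssertionError(f"traceback failed at M({i},{j})")


def _traceback(S, V, M, M1, F):
    n = len(S)
    pairs = np.full(n, -1, dtype=np.int64)
    jj = n
    while jj > 0:
        if F[jj] == F[jj - 1]:
            jj -= 1
            continue
        j = jj - 1
        for i in range(0, j - MIN_HAIRPIN):
            if PAIR_TYPE[S[i], S[j]] > 0 and V[i, j] < INF:
                if F[i] + V[i, j] + e_ext_stem(S, i, j) == F[jj]:
                    _trace_V(S, V, M, M1, pairs, i, j)
                    jj = i
                    break
        else:
            raise AssertionError(f"traceback failed at F({jj})")
    structure = "".join(
        "." if pairs[k] < 0 else ("(" if pairs[k] > k else ")") for k in range(n)
    )
    return structure


def fold_mfe(sequence: str) -> tuple[str, float]:
    """Fold one RNA sequence; returns (dot-bracket, MFE in kcal/mol).

    Sequences whose best structure is not strictly stabilizing (energy >= 0)
    are reported as the open chain with MFE exactly 0.
    """
    S = encode(sequence)
    n = len(S)
    if n <= MIN_HAIRPIN + 1:
        return "." * n, 0.0
    V, M, M1, F = _fill(S)
    e = int(F[n])
    if e >= 0:
        return "." * n, 0.0
    structure = _traceback(S, V, M, M1, F)
    return structure, e / 100.0


def energies(sequence: str) -> int:
    """Integer MFE (0.01 kcal/mol) without traceback; negative or zero."""
    S = encode(sequence)
    if len(S) <= MIN_HAIRPIN + 1:
        return 0
    _, _, _, F = _fill(S)
    return min(0, int(F[len(S)]))
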