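"""Simplified pair-maximization folder (dependency-free reference backend).

A Nussinov-flavoured dynamic program over the legal pairs AU/UA/GC/CG/GU/UG
with the usual minimum hairpin loop of 3, scored by a deliberately crude
energy: −1 per stacked pair adjacency (pairs (i,j) and (i+1,j−1) both
present) and +3 per hairpin loop; every other loop context is free.  The
score is a model-specific pseudo-energy, not kcal/mol — the backend exists
so that structural invariants and pipelines can be exercised without the
nearest-neighbor machinery.  When the optimal score is non-negative the
open chain with MFE 0 is returned.
"""

from __future__ import annotations

import numpy as np

from .params import INF, MIN_HAIRPIN, PAIR_TYPE, encode
from .structure import parse_dotbracket, pairs_to_dotbracket

__all__ = ["fold_simple", "simple_structure_energy"]

HAIRPIN_COST = 3
STACK_BONUS = -1


def _fill(S: np.ndarray):
    n = len(S)
    V = np.full((n, n), INF, dtype=np.int64)
    Wp = np.full((n, n), INF, dtype=np.int64)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            if PAIR_TYPE[S[i], S[j]] > 0 and d > MIN_HAIRPIN:
                best = HAIRPIN_COST
                if j - i - 1 > MIN_HAIRPIN + 1 and PAIR_TYPE[S[i + 1], S[j - 1]] > 0:
                    if V[i + 1, j - 1] < INF:
                        best = min(best, V[i + 1, j - 1] + STACK_BONUS)
                if Wp[i + 1, j - 1] < INF:
                    best = min(best, Wp[i + 1, j - 1])
                V[i, j] = best
            w = Wp[i + 1, j] if i + 1 <= j else INF
            for l in range(i + MIN_HAIRPIN + 1, j + 1):
                if V[i, l] < INF:
                    rest = 0
                    if l + 1 <= j and Wp[l + 1, j] < INF and Wp[l + 1, j] < 0:
                        rest = Wp[l + 1, j]
                    w = min(w, V[i, l] + rest)
            Wp[i, j] = w
    return V, Wp


def _trace_V(S, V, Wp, pairs, i, j):
    pairs[i] = j
    pairs[j] = i
    t = V[i, j]
    if t == HAIRPIN_COST:
        return
    if (
        j - i - 1 > MIN_HAIRPIN + 1
        and PAIR_TYPE[S[i + 1], S[j - 1]] > 0
        and V[i + 1, j - 1] < INF
        and V[i + 1, j - 1] + STACK_BONUS == t
    ):
        _trace_V(S, V, Wp, pairs, i + 1, j - 1)
        return
    assert Wp[i + 1, j - 1] == t
    _trace_Wp(S, V, Wp, pairs, i + 1, j - 1)


def _trace_Wp(S, V, Wp, pairs, i, j):
    while True:
        t = Wp[i, j]
        if i + 1 <= j and Wp[i + 1, j] == t:
            i += 1
            continue
        for l in range(i + MIN_HAIRPIN + 1, j + 1):
            if V[i, l] < INF:
                rest = 0
                take_rest = False
                if l + 1 <= j and Wp[l + 1, j] < INF and Wp[l + 1, j] < 0:
                    rest = Wp[l + 1, j]
                    take_rest = True
                if V[i, l] + rest == t:
                    _trace_V(S, V, Wp, pairs, i, l)
                    if take_rest:
                        i = l + 1
                        break
                    return
        else:
            raise AssertionError(f"traceback failed at Wp({i},{j})")


def fold_simple(sequence: str) -> tuple[str, float]:
    """Fold with the simplified score; returns (dot-bracket, score)."""
    S = encode(sequence)
    n = len(S)
    if n <= MIN_HAIRPIN + 1:
        return "." * n, 0.0
    V, Wp = _fill(S)
    e = int(Wp[0, n - 1]) if Wp[0, n - 1] < INF else 0
    if e >= 0:
        return "." * n, 0.0
    pairs = np.full(n, -1, dtype=np.int64)
    _trace_Wp(S, V, Wp, pairs, 0, n - 1)
    return pairs_to_dotbracket(pairs), float(e)


def simple_structure_energy(sequence: str, structure: str) -> float:
    """Score an explicit structure under the simplified model (oracle use)."""
    S = encode(sequence)
    pairs = parse_dotbracket(structure)
    n = len(S)
    total = 0
    for i in range(n):
        j = int(pairs[i])
        if j <= i:
            continue
        has_child = np.any(pairs[i + 1 : j] >= 0)
        if not has_child:
            total += HAIRPIN_COST
        elif pairs[i + 1] == j - 1:
            total += STACK_BONUS
    return float(total)
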