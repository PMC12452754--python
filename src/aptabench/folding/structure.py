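"""Dot-bracket utilities: parsing, validation and loop-decomposition scoring.

``structure_energy`` evaluates an explicit structure by decomposing it into
exterior, hairpin, interior and multibranch loops and summing the same
energy primitives the dynamic program uses.  Because the decomposition is
independent of the DP recursions, exhaustive enumeration plus this evaluator
serves as a brute-force oracle for the folding kernels on short sequences.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

from .params import MIN_HAIRPIN, ML_CLOSING, ML_UNPAIRED, PAIR_TYPE, REVERSE_PAIR, encode
from .zuker import e_ext_stem, e_hairpin, e_interior, e_ml_stem

__all__ = [
    "parse_dotbracket",
    "pairs_to_dotbracket",
    "validate_structure",
    "structure_energy",
    "enumerate_structures",
    "count_pairs",
]


def parse_dotbracket(structure: str) -> np.ndarray:
    """Map a dot-bracket string to a partner array (−1 for unpaired)."""
    pairs = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for k, ch in enumerate(structure):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {k + 1}")
            i = stack.pop()
            pairs[i] = k
            pairs[k] = i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at position {k + 1}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return pairs


def pairs_to_dotbracket(pairs: np.ndarray) -> str:
    return "".join(
        "." if pairs[k] < 0 else ("(" if pairs[k] > k else ")") for k in range(len(pairs))
    )


def count_pairs(structure: str) -> int:
    return structure.count("(")


def validate_structure(sequence: str, structure: str) -> None:
    """Check bracket balance, pair legality (AU/UA/GC/CG/GU/UG) and the
    minimum hairpin loop; raises ValueError with the offending position."""
    if len(sequence) != len(structure):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    S = encode(sequence)
    pairs = parse_dotbracket(structure)
    for i in range(len(S)):
        j = int(pairs[i])
        if j > i:
            if PAIR_TYPE[S[i], S[j]] == 0:
                raise ValueError(
                    f"illegal pair {sequence[i]}{sequence[j]} at positions "
                    f"({i + 1}, {j + 1})"
                )
            if j - i - 1 < MIN_HAIRPIN and not np.any(pairs[i + 1 : j] >= 0):
                raise ValueError(
                    f"hairpin loop at ({i + 1}, {j + 1}) encloses {j - i - 1} "
                    f"unpaired residues; minimum is {MIN_HAIRPIN}"
                )


def _children(pairs: np.ndarray, i: int, j: int) -> list[tuple[int, int]]:
    """Directly enclosed pairs of the loop closed by (i, j)."""
    out = []
    k = i + 1
    while k < j:
        if pairs[k] > k:
            out.append((k, int(pairs[k])))
            k = int(pairs[k]) + 1
        else:
            k += 1
    return out


def structure_energy(sequence: str, structure: str) -> float:
    """Free energy (kcal/mol) of an explicit structure under the package's
    nearest-neighbor model, by loop decomposition."""
    validate_structure(sequence, structure)
    S = encode(sequence)
    pairs = parse_dotbracket(structure)
    n = len(S)
    total = 0
    # exterior loop stems
    k = 0
    while k < n:
        if pairs[k] > k:
            total += e_ext_stem(S, k, int(pairs[k]))
            k = int(pairs[k]) + 1
        else:
            k += 1
    # closed loops
    for i in range(n):
        j = int(pairs[i])
        if j <= i:
            continue
        kids = _children(pairs, i, j)
        if not kids:
            total += e_hairpin(S, i, j)
        elif len(kids) == 1:
            p, q = kids[0]
            total += e_interior(S, i, j, p, q)
        else:
            rpt = REVERSE_PAIR[PAIR_TYPE[S[i], S[j]]]
            total += ML_CLOSING + e_ml_stem(rpt, S[j - 1], S[i + 1])
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in kids)
            total += ML_UNPAIRED * unpaired
            for p, q in kids:
                total += e_ml_stem(PAIR_TYPE[S[p], S[q]], S[p - 1], S[q + 1])
    return total / 100.0


def enumerate_structures(sequence: str) -> Iterator[str]:
    """Yield every legal secondary structure of a (short) sequence.

    Legal means: non-crossing pairs drawn from AU/UA/GC/CG/GU/UG with every
    hairpin loop enclosing at least MIN_HAIRPIN unpaired residues.  The open
    chain is yielded first.  Intended for brute-force oracles (n ≲ 12).
    """
    S = encode(sequence)
    n = len(S)

    def rec(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        # all pair sets on region [i, j]
        if j - i + 1 <= MIN_HAIRPIN + 1:
            yield ()
            return
        # i unpaired
        yield from rec(i + 1, j)
        # i paired with l
        for l in range(i + MIN_HAIRPIN + 1, j + 1):
            if PAIR_TYPE[S[i], S[l]] > 0:
                for inner in rec(i + 1, l - 1):
                    for outer in rec(l + 1, j):
                        yield ((i, l),) + inner + outer

    for pairset in rec(0, n - 1):
        arr = np.full(n, -1, dtype=np.int64)
        for a, b in pairset:
            arr[a] = b
            arr[b] = a
        yield pairs_to_dotbracket(arr)
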