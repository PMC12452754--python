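"""Nearest-neighbor free-energy parameterization for RNA secondary structure.

Turner-style rules at 37 °C, in units of 0.01 kcal/mol (integer arithmetic):
Watson–Crick and G·U wobble stack free energies, hairpin/bulge/internal loop
initiations with Jacobson–Stockmayer extrapolation, terminal AU/GU helix-end
penalties, an affine multiloop model and both-side dangling ends (the
``dangles=2`` convention of common folding engines, where a stem inside a
multiloop or in the exterior loop always collects 5' and 3' dangle terms
from its flanking nucleotides).

Core stack and loop-initiation values are transcribed from the published
nearest-neighbor literature.  The full terminal-mismatch and special
tetraloop tables of the published model are not reproduced; terminal
mismatches are approximated by closing-pair-class values plus the published
first-mismatch bonuses (G·A, U·U, G·G), and no tetraloop bonus table is
applied.  Engines built on these tables are therefore *Turner-style*, not a
bit-exact replica of any particular reference engine; docs/methods.md
details the approximation.
"""

from __future__ import annotations

import math

import numpy as np

#: Residue encoding used by every folding kernel.
BASES = "ACGU"
A, C, G, U = 0, 1, 2, 3

#: Pair-type codes (0 = not pairable).
N_PAIR_TYPES = 7  # 1..6 used
PAIR_NAMES = {1: "CG", 2: "GC", 3: "GU", 4: "UG", 5: "AU", 6: "UA"}

#: Largest number of unpaired nucleotides considered in one interior loop.
MAXLOOP = 30

#: Minimum unpaired length of a hairpin loop.
MIN_HAIRPIN = 3

INF = 10_000_000

#: 1.75·R·T at 37 °C, for entropic loop-size extrapolation (0.01 kcal/mol).
_LXC = 107.85

_LOOP_ARRAY_SIZE = 512


def _pair_table() -> np.ndarray:
    pt = np.zeros((4, 4), dtype=np.int32)
    pt[C, G] = 1
    pt[G, C] = 2
    pt[G, U] = 3
    pt[U, G] = 4
    pt[A, U] = 5
    pt[U, A] = 6
    return pt


PAIR_TYPE = _pair_table()

#: Reversed orientation of each pair type (CG<->GC, GU<->UG, AU<->UA).
REVERSE_PAIR = np.array([0, 2, 1, 4, 3, 6, 5], dtype=np.int32)

#: Pair types carrying a terminal AU/GU helix-end penalty (any pair with U).
_IS_AU_GU = np.array([0, 0, 0, 1, 1, 1, 1], dtype=np.int32)

#: Helix-end penalty, applied per AU/GU closing pair at helix ends
#: (exterior, multiloop branches, hairpin closures, bulges > 1 nt).
TERMINAL_AU = 50

#: Internal-loop AU/GU closure penalty (per side).
INTERNAL_AU_CLOSURE = 70


def _stack_table() -> np.ndarray:
    """stack[p1][p2]: pair p2 = (i+1, j-1) stacked directly inside p1 = (i, j).

    Values are ΔG°37 of the published Watson–Crick set and the G·U wobble
    set, 0.01 kcal/mol.
    """
    s = np.full((N_PAIR_TYPES, N_PAIR_TYPES), INF, dtype=np.int32)
    #          CG    GC    GU    UG    AU    UA
    s[1, 1:] = (-326, -236, -141, -211, -211, -208)  # outer CG
    s[2, 1:] = (-342, -326, -153, -251, -235, -224)  # outer GC
    s[3, 1:] = (-251, -211, +47, +30, -100, -136)    # outer GU
    s[4, 1:] = (-153, -141, -57, +47, -127, -55)     # outer UG
    s[5, 1:] = (-224, -208, -55, -136, -93, -110)    # outer AU
    s[6, 1:] = (-235, -211, -127, -100, -133, -93)   # outer UA
    return s


STACK = _stack_table()


def _extrapolate(base: list[float], anchor: int) -> np.ndarray:
    """Loop initiation table with ln-extrapolation beyond the listed sizes."""
    arr = np.full(_LOOP_ARRAY_SIZE, INF, dtype=np.int32)
    for size, val in enumerate(base):
        if val < INF:
            arr[size] = int(round(val))
    last = base[anchor]
    for size in range(anchor + 1, _LOOP_ARRAY_SIZE):
        if arr[size] >= INF:
            arr[size] = int(round(last + _LXC * math.log(size / anchor)))
    return arr


# Hairpin loop initiation ΔG°37 by unpaired size (3..9 published, then
# Jacobson–Stockmayer extrapolation).
HAIRPIN_INIT = _extrapolate(
    [INF, INF, INF, 540, 560, 570, 540, 600, 550, 640], anchor=9
)

# Bulge loop initiation by unpaired size (1..6 published).
BULGE_INIT = _extrapolate(
    [INF, 380, 280, 320, 360, 400, 440], anchor=6
)

# Internal loop initiation by total unpaired size.  Sizes 2 (1×1) and 3
# (1×2) are handled as near-special cases with their own base values.
INTERNAL_INIT = _extrapolate(
    [INF, INF, INF, 160, 110, 200, 200], anchor=6
)

#: 1×1 internal loop base value (plus closures and G·G bonus below).
INT11_BASE = 80
#: Bonus when a 1×1 loop's mismatch is G·G.
INT11_GG_BONUS = -120

#: Asymmetry (Ninio) penalty: per |n1 − n2| nucleotide, capped.
NINIO_PER_NT = 60
NINIO_MAX = 300

# Multiloop affine model: closing penalty + per-branch penalty (the closing
# pair counts as a branch); unpaired bases inside the loop are free.
ML_CLOSING = 340
ML_BRANCH = 40
ML_UNPAIRED = 0

# Hairpin terminal-mismatch approximation (loops of size >= 4): a
# closing-pair-class base value plus published first-mismatch bonuses.
_HAIRPIN_MM_BASE = np.array([0, -120, -120, -60, -60, -60, -60], dtype=np.int32)

#: First-mismatch bonuses, by unordered mismatch identity.
MM_BONUS_GA = -90   # G·A or A·G
MM_BONUS_UU = -90   # U·U (hairpins); internal loops use -70
MM_BONUS_GG = -80   # G·G (hairpins only)
INTERNAL_MM_GA = -90
INTERNAL_MM_UU = -70


def _dangle_tables() -> tuple[np.ndarray, np.ndarray]:
    """5' and 3' dangle energies, dangle[pair][base].

    Orientation: for a helix closed by pair (i, j) seen from outside, the 5'
    dangle is the nucleotide before i and the 3' dangle the one after j.
    G·U rows reuse the corresponding A·U/U·A values.
    """
    d5 = np.zeros((N_PAIR_TYPES, 4), dtype=np.int32)
    d3 = np.zeros((N_PAIR_TYPES, 4), dtype=np.int32)
    #              A    C    G    U
    d5[1] = (-50, -30, -20, -10)   # CG
    d5[2] = (-20, -30, -0, -0)     # GC
    d5[5] = (-30, -10, -20, -20)   # AU
    d5[6] = (-30, -30, -40, -20)   # UA
    d5[3] = d5[5]                  # GU ~ AU
    d5[4] = d5[6]                  # UG ~ UA
    d3[1] = (-110, -40, -130, -60)   # CG
    d3[2] = (-170, -80, -170, -120)  # GC
    d3[5] = (-80, -50, -80, -60)     # AU
    d3[6] = (-70, -10, -70, -10)     # UA
    d3[3] = d3[5]
    d3[4] = d3[6]
    return d5, d3


DANGLE5, DANGLE3 = _dangle_tables()

HAIRPIN_MM_BASE = _HAIRPIN_MM_BASE
IS_AU_GU = _IS_AU_GU

#: Human-readable descriptor recorded in output provenance.
PARAMETER_SET = "turner-style nearest-neighbor, 37C, d2 dangles, approx mismatches, v1"


def encode(sequence: str) -> np.ndarray:
    """Encode an RNA string to the 0..3 integer alphabet of the kernels."""
    try:
        return np.array([BASES.index(ch) for ch in sequence], dtype=np.int32)
    except ValueError:
        bad = next(ch for ch in sequence if ch not in BASES)
        raise ValueError(f"invalid residue {bad!r}; expected one of A/C/G/U") from None
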