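"""Base-randomization generation of virtual RNA aptamer libraries.

The generator draws each residue independently and uniformly from a fixed
alphabet (default A, U, G, C) using a single seeded pseudorandom stream,
rejecting whole sequences on collision so that every emitted sequence is
unique.  Two library shapes are supported: *fixed* length (every sequence
``n`` residues long) and *randomized* length (lengths drawn uniformly from
an inclusive integer range ``[j, k]``).

The module also provides exact sequence-space counting (``size ** n`` with
arbitrary precision) and lazy exhaustive enumeration of all sequences of a
given length, which back the length-threshold folding scan.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "RNA_ALPHABET",
    "LengthSpec",
    "GeneratorConfig",
    "AptamerSequence",
    "AptamerLibrary",
    "FeasibilityError",
    "ExhaustionError",
    "draw_base",
    "draw_length",
    "generate_sequence",
    "generate_library",
    "sequence_space_size",
    "library_space_size",
    "enumerate_all",
]

#: Guard for exhaustive enumeration; 4^12 ≈ 1.7e7 is the most a laptop-class
#: run should stream without an explicit override.
ENUMERATION_GUARD = 12

#: Duplicate rejection-resampling cap, as a multiple of the requested count.
MAX_ATTEMPT_FACTOR = 1000


class FeasibilityError(ValueError):
    """Requested more unique sequences than the sequence space contains."""


class ExhaustionError(RuntimeError):
    """Resampling failed to find enough unique sequences within the cap."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet; order fixes both sampling index and
    lexicographic enumeration order."""

    symbols: tuple[str, ...] = ("A", "U", "G", "C")

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        if not self.symbols:
            raise ValueError("alphabet must not be empty")
        for s in self.symbols:
            if len(s) != 1:
                raise ValueError(f"alphabet symbols must be single characters, got {s!r}")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __str__(self) -> str:
        return "".join(self.symbols)


RNA_ALPHABET = Alphabet(("A", "U", "G", "C"))


@dataclass(frozen=True)
class LengthSpec:
    """Fixed length ``n`` or uniform integer length on the inclusive
    range ``[j, k]``."""

    mode: str  # "fixed" | "range"
    n: int | None = None
    j: int | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.n is None or self.n < 1:
                raise ValueError("fixed mode requires n >= 1")
        elif self.mode == "range":
            if self.j is None or self.k is None:
                raise ValueError("range mode requires bounds j and k")
            if not (1 <= self.j <= self.k):
                raise ValueError(f"range mode requires 1 <= j <= k, got [{self.j}, {self.k}]")
        else:
            raise ValueError(f"unknown length mode {self.mode!r}")

    @classmethod
    def fixed(cls, n: int) -> "LengthSpec":
        return cls(mode="fixed", n=n)

    @classmethod
    def uniform_range(cls, j: int, k: int) -> "LengthSpec":
        return cls(mode="range", j=j, k=k)

    @property
    def is_fixed(self) -> bool:
        return self.mode == "fixed"

    @property
    def max_length(self) -> int:
        return self.n if self.is_fixed else self.k  # type: ignore[return-value]

    def __str__(self) -> str:
        return f"fixed:{self.n}" if self.is_fixed else f"range:{self.j}:{self.k}"


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a generated library: seed, count, length
    specification and alphabet."""

    seed: int
    count: int
    length_spec: LengthSpec
    alphabet: Alphabet = RNA_ALPHABET

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class AptamerSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must contain at least one residue")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass
class AptamerLibrary:
    """Ordered collection of pairwise-distinct sequences.

    ``config`` is present for generated libraries and ``None`` for imported
    ones (e.g. read from FASTA), in which case ``mode`` reflects whether all
    observed lengths agree.
    """

    sequences: list[AptamerSequence]
    config: GeneratorConfig | None = None
    source: str = "generated"

    def __post_init__(self) -> None:
        residues = [s.residues for s in self.sequences]
        if len(set(residues)) != len(residues):
            raise ValueError("library sequences must be pairwise distinct")
        if self.config is not None:
            spec = self.config.length_spec
            for s in self.sequences:
                if spec.is_fixed and s.length != spec.n:
                    raise ValueError(f"{s.id}: length {s.length} != fixed length {spec.n}")
                if not spec.is_fixed and not (spec.j <= s.length <= spec.k):
                    raise ValueError(
                        f"{s.id}: length {s.length} outside [{spec.j}, {spec.k}]"
                    )

    @property
    def mode(self) -> str:
        if self.config is not None:
            return "fixed" if self.config.length_spec.is_fixed else "randomized"
        return "fixed" if len({s.length for s in self.sequences}) == 1 else "randomized"

    @property
    def alphabet(self) -> Alphabet:
        return self.config.alphabet if self.config is not None else RNA_ALPHABET

    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.sequences], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[AptamerSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> AptamerSequence:
        return self.sequences[i]


def draw_base(r: float, alphabet: Alphabet = RNA_ALPHABET) -> str:
    """Map one uniform variate ``r ∈ [0, 1)`` to a residue.

    The residue is ``symbols[floor(r * size)]``; because ``r < 1`` strictly,
    the index never reaches ``size``.
    """
    if not (0.0 <= r < 1.0):
        raise ValueError(f"r must lie in [0, 1), got {r}")
    return alphabet.symbols[int(r * alphabet.size)]


def draw_length(spec: LengthSpec, rng: np.random.Generator) -> int:
    """Uniform integer length from the inclusive range of a range-mode spec."""
    if spec.is_fixed:
        raise ValueError("draw_length requires a range-mode LengthSpec")
    return int(rng.integers(spec.j, spec.k + 1))


def _draw_indices(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    # Vectorized form of draw_base: floor(r * size) over a block of uniforms.
    return (rng.random(n) * size).astype(np.intp)


def generate_sequence(
    n: int, alphabet: Alphabet = RNA_ALPHABET, rng: np.random.Generator | None = None,
    id: str = "seq",
) -> AptamerSequence:
    """One sequence of ``n`` independent uniform residue draws."""
    if n < 1:
        raise ValueError(f"sequence length must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng()
    idx = _draw_indices(n, alphabet.size, rng)
    return AptamerSequence(id=id, residues="".join(alphabet.symbols[i] for i in idx))


def sequence_space_size(alphabet_size: int, n: int) -> int:
    """Exact count of distinct sequences of length ``n``: ``alphabet_size ** n``.

    Python integers make this exact at any length (4**60 overflows 64 bits).
    """
    if alphabet_size < 1 or n < 1:
        raise ValueError("alphabet_size and n must be >= 1")
    return alphabet_size ** n


def library_space_size(alphabet_size: int, spec: LengthSpec) -> int:
    """Exact count of distinct sequences admissible under a length spec."""
    if spec.is_fixed:
        return sequence_space_size(alphabet_size, spec.n)
    return sum(sequence_space_size(alphabet_size, n) for n in range(spec.j, spec.k + 1))


def generate_library(config: GeneratorConfig) -> AptamerLibrary:
    """Generate ``config.count`` pairwise-distinct sequences.

    Duplicates are handled by rejection: a colliding sequence is discarded and
    redrawn in full.  Expected time is O(m·n) while the library is a
    vanishing fraction of the sequence space; a hard cap of
    ``MAX_ATTEMPT_FACTOR × count`` attempts guards the loop.
    """
    space = library_space_size(config.alphabet.size, config.length_spec)
    if config.count > space:
        raise FeasibilityError(
            f"cannot generate {config.count} unique sequences: the sequence space "
            f"under {config.length_spec} holds only {space}"
        )
    rng = np.random.default_rng(config.seed)
    spec = config.length_spec
    seen: set[str] = set()
    ordered: list[str] = []
    attempts = 0
    cap = MAX_ATTEMPT_FACTOR * config.count
    while len(ordered) < config.count:
        if attempts >= cap:
            raise ExhaustionError(
                f"gave up after {attempts} attempts ({len(ordered)} unique of "
                f"{config.count} requested); the space may be nearly exhausted"
            )
        attempts += 1
        n = spec.n if spec.is_fixed else draw_length(spec, rng)
        idx = _draw_indices(n, config.alphabet.size, rng)
        residues = "".join(config.alphabet.symbols[i] for i in idx)
        if residues not in seen:
            seen.add(residues)
            ordered.append(residues)
    sequences = [
        AptamerSequence(id=f"aptamer{i + 1}", residues=res)
        for i, res in enumerate(ordered)
    ]
    return AptamerLibrary(sequences=sequences, config=config)


def enumerate_all(
    n: int,
    alphabet: Alphabet = RNA_ALPHABET,
    allow_large: bool = False,
) -> Iterator[AptamerSequence]:
    """Lazily yield every length-``n`` sequence once, lexicographic in
    alphabet order.

    Lengths above ``ENUMERATION_GUARD`` are refused unless ``allow_large`` is
    set, since the stream grows as ``size ** n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > ENUMERATION_GUARD and not allow_large:
        raise ValueError(
            f"enumerating length {n} would stream {alphabet.size}**{n} sequences; "
            f"pass allow_large=True to override the n <= {ENUMERATION_GUARD} guard"
        )
    for i, combo in enumerate(itertools.product(alphabet.symbols, repeat=n)):
        yield AptamerSequence(id=f"enum{n}_{i}", residues="".join(combo))
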