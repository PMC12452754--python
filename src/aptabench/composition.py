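"""Base, adjacent-pair and k-mer composition of aptamer libraries.

Dataset-level summaries follow one-way-ANOVA bookkeeping: per base the table
reports Count (number of sequences), Sum (total occurrences), Average
(mean occurrences per sequence) and sample Variance (denominator Count − 1).

The module also exposes the closed-form prediction for the dataset mean of
each base: with uniform residue draws the expected count of base *x* in a
length-``N`` sequence is ``P(x) · N`` with ``P(x) = 1/|alphabet|``; under a
uniform integer length on ``[j, k]`` the dataset mean is ``P(x) · M`` where
``M = (j + k)/2`` is the median of consecutive integers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generator import (
    Alphabet,
    AptamerLibrary,
    AptamerSequence,
    LengthSpec,
    RNA_ALPHABET,
)

__all__ = [
    "CompositionRecord",
    "AdjacencyRecord",
    "LengthPrediction",
    "base_counts",
    "count_matrix",
    "composition_summary",
    "per_sequence_table",
    "adjacent_counts",
    "adjacency_table",
    "kmer_names",
    "kmer_frequencies",
    "predicted_base_mean",
    "proposition_check",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionRecord:
    """Per-sequence base counts and percentage frequencies."""

    id: str
    counts: dict[str, int]
    frequencies: dict[str, float]  # percent of sequence length

    @property
    def length(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class AdjacencyRecord:
    """Counts of the 16 ordered dinucleotides (overlapping windows)."""

    id: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class LengthPrediction:
    """Closed-form predicted per-base dataset mean for a length spec."""

    p: float              # P(x) = 1 / alphabet size
    effective_length: float  # N (fixed) or M = (j+k)/2 (range)
    predicted_mean: float

    @property
    def value(self) -> float:
        return self.predicted_mean


def _validate(seq: AptamerSequence, alphabet: Alphabet) -> None:
    for pos, res in enumerate(seq.residues):
        if res not in alphabet:
            raise ValueError(
                f"{seq.id}: residue {res!r} at position {pos + 1} is not in "
                f"alphabet {alphabet}"
            )


def base_counts(seq: AptamerSequence, alphabet: Alphabet = RNA_ALPHABET) -> CompositionRecord:
    """Exact per-base counts and percent frequencies for one sequence."""
    _validate(seq, alphabet)
    counts = {s: seq.residues.count(s) for s in alphabet.symbols}
    n = seq.length
    freqs = {s: 100.0 * c / n for s, c in counts.items()}
    return CompositionRecord(id=seq.id, counts=counts, frequencies=freqs)


def count_matrix(library: AptamerLibrary, alphabet: Alphabet | None = None) -> pd.DataFrame:
    """Per-sequence base counts: one row per sequence, one column per base."""
    if len(library) == 0:
        raise ValueError("library is empty")
    alphabet = alphabet or library.alphabet
    rows = []
    for seq in library:
        rec = base_counts(seq, alphabet)
        rows.append({"id": rec.id, **rec.counts})
    return pd.DataFrame(rows).set_index("id")


def composition_summary(
    library: AptamerLibrary, alphabet: Alphabet | None = None
) -> pd.DataFrame:
    """Dataset summary: one row per base with Count, Sum, Average, Variance.

    Variance is the sample variance (denominator Count − 1), matching
    standard ANOVA bookkeeping.
    """
    mat = count_matrix(library, alphabet)
    rows = []
    for base in mat.columns:
        col = mat[base].to_numpy(dtype=float)
        rows.append(
            {
                "Base": base,
                "Count": len(col),
                "Sum": int(col.sum()),
                "Average": float(col.mean()),
                "Variance": float(col.var(ddof=1)) if len(col) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def per_sequence_table(
    library: AptamerLibrary, alphabet: Alphabet | None = None
) -> pd.DataFrame:
    """Per-sequence composition: id, length, counts and percent frequencies."""
    alphabet = alphabet or library.alphabet
    rows = []
    for seq in library:
        rec = base_counts(seq, alphabet)
        row: dict[str, object] = {"id": rec.id, "length": seq.length}
        row.update({f"count_{b}": c for b, c in rec.counts.items()})
        row.update({f"pct_{b}": f for b, f in rec.frequencies.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _dinucleotides(alphabet: Alphabet) -> list[str]:
    return ["".join(p) for p in itertools.product(alphabet.symbols, repeat=2)]


def adjacent_counts(
    seq: AptamerSequence, alphabet: Alphabet = RNA_ALPHABET
) -> AdjacencyRecord:
    """Ordered dinucleotide counts over overlapping windows (no wrap-around).

    A length-1 sequence yields an all-zero record with a logged warning so
    that imported degenerate libraries do not abort batch runs.
    """
    _validate(seq, alphabet)
    counts = dict.fromkeys(_dinucleotides(alphabet), 0)
    if seq.length < 2:
        logger.warning("%s: length %d < 2, adjacency record is all-zero", seq.id, seq.length)
        return AdjacencyRecord(id=seq.id, counts=counts)
    for i in range(seq.length - 1):
        counts[seq.residues[i : i + 2]] += 1
    return AdjacencyRecord(id=seq.id, counts=counts)


def adjacency_table(
    library: AptamerLibrary, alphabet: Alphabet | None = None
) -> pd.DataFrame:
    """One row per sequence, one column per ordered dinucleotide."""
    alphabet = alphabet or library.alphabet
    rows = [{"id": s.id, **adjacent_counts(s, alphabet).counts} for s in library]
    return pd.DataFrame(rows).set_index("id")


def kmer_names(kmax: int, alphabet: Alphabet = RNA_ALPHABET) -> list[str]:
    """All k-mers for k in 1..kmax, ordered by k then lexicographically."""
    names: list[str] = []
    for k in range(1, kmax + 1):
        names.extend("".join(p) for p in itertools.product(alphabet.symbols, repeat=k))
    return names


def kmer_frequencies(
    seq: AptamerSequence, kmax: int = 3, alphabet: Alphabet = RNA_ALPHABET
) -> tuple[dict[str, int], dict[str, float]]:
    """Overlapping-window k-mer counts and frequencies for k = 1..kmax.

    Frequencies for a given k are normalized by the window count
    ``length − k + 1``.
    """
    if not (1 <= kmax <= seq.length):
        raise ValueError(f"kmax must lie in [1, {seq.length}], got {kmax}")
    _validate(seq, alphabet)
    counts = dict.fromkeys(kmer_names(kmax, alphabet), 0)
    for k in range(1, kmax + 1):
        for i in range(seq.length - k + 1):
            counts[seq.residues[i : i + k]] += 1
    freqs = {name: counts[name] / (seq.length - len(name) + 1) for name in counts}
    return counts, freqs


def predicted_base_mean(
    spec: LengthSpec, alphabet: Alphabet = RNA_ALPHABET
) -> LengthPrediction:
    """Closed-form dataset mean per base: P(x)·N (fixed) or P(x)·M (range)."""
    p = 1.0 / alphabet.size
    if spec.is_fixed:
        eff = float(spec.n)
    else:
        eff = (spec.j + spec.k) / 2.0  # median of consecutive integers
    return LengthPrediction(p=p, effective_length=eff, predicted_mean=p * eff)


def proposition_check(
    library: AptamerLibrary,
    spec: LengthSpec | None = None,
    alphabet: Alphabet | None = None,
) -> pd.DataFrame:
    """Compare observed per-base dataset means with the closed-form prediction.

    Returns one row per base with observed mean, predicted mean, absolute
    deviation, the standard error of the observed mean, and a pass flag at
    ``|observed − predicted| ≤ 3·SE``.
    """
    if spec is None:
        if library.config is None:
            raise ValueError(
                "imported library carries no generation config; pass an explicit "
                "LengthSpec"
            )
        spec = library.config.length_spec
    alphabet = alphabet or library.alphabet
    prediction = predicted_base_mean(spec, alphabet)
    mat = count_matrix(library, alphabet)
    m = len(mat)
    rows = []
    for base in mat.columns:
        col = mat[base].to_numpy(dtype=float)
        obs = float(col.mean())
        se = float(col.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan")
        dev = abs(obs - prediction.predicted_mean)
        rows.append(
            {
                "Base": base,
                "Observed": obs,
                "Predicted": prediction.predicted_mean,
                "AbsDeviation": dev,
                "SE": se,
                "Pass": bool(m == 1 and dev == 0.0) if m == 1 else bool(dev <= 3 * se),
            }
        )
    return pd.DataFrame(rows)
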