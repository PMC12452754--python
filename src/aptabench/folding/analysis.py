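"""Dataset-level folding characterization.

Zero-MFE (non-folding) fractions, MFE order statistics, length–MFE and
composition–MFE Pearson correlations, and the length-threshold scan that
counts how many sequences of each length attain a strictly negative MFE
(exhaustively below a cap, by seeded uniform sampling above it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..generator import (
    Alphabet,
    AptamerLibrary,
    AptamerSequence,
    RNA_ALPHABET,
    enumerate_all,
    generate_sequence,
    sequence_space_size,
)
from .backends import DEFAULT_BACKEND, FoldingBackend, FoldResult, get_backend

__all__ = [
    "MfeSummary",
    "LengthScanRow",
    "fold_library",
    "mfe_summary",
    "length_mfe_correlation",
    "feature_mfe_correlations",
    "length_threshold_scan",
    "scan_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MfeSummary:
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    zero_count: int
    zero_fraction: float
    most_stable_ids: tuple[str, ...]
    failed: int = 0

    @property
    def zero_percent(self) -> float:
        return 100.0 * self.zero_fraction


@dataclass(frozen=True)
class LengthScanRow:
    """One length in the threshold scan.

    ``arrangements`` is the exact sequence-space size 4**n; ``sampled_total``
    is how many sequences were actually folded; ``zeta`` is the indicator
    that folding is possible at this length (0 for n <= 7, 1 above).
    """

    length: int
    arrangements: int
    sampled_total: int
    nonzero_mfe_count: int
    exhaustive: bool

    @property
    def zeta(self) -> int:
        return 0 if self.length <= 7 else 1

    @property
    def nonzero_fraction(self) -> float:
        return self.nonzero_mfe_count / self.sampled_total


def fold_library(
    library: AptamerLibrary, backend: str | FoldingBackend = DEFAULT_BACKEND
) -> list[FoldResult]:
    """Fold every sequence; individual failures are logged, not fatal."""
    bk = get_backend(backend)
    results: list[FoldResult] = []
    for seq in library:
        try:
            results.append(bk.fold(seq))
        except Exception:  # pragma: no cover - defensive batch behavior
            logger.warning("fold failed for %s; skipping", seq.id, exc_info=True)
    return results


def mfe_summary(
    library: AptamerLibrary,
    backend: str | FoldingBackend = DEFAULT_BACKEND,
    results: list[FoldResult] | None = None,
    n_most_stable: int = 2,
) -> MfeSummary:
    """Order statistics of MFE plus the non-folding (MFE = 0) fraction."""
    if len(library) == 0:
        raise ValueError("library is empty")
    if results is None:
        results = fold_library(library, backend)
    mfes = np.array([r.mfe for r in results])
    order = np.argsort(mfes)
    zero = int(np.sum(mfes == 0.0))
    return MfeSummary(
        n=len(results),
        minimum=float(mfes.min()),
        q1=float(np.percentile(mfes, 25)),
        median=float(np.percentile(mfes, 50)),
        q3=float(np.percentile(mfes, 75)),
        maximum=float(mfes.max()),
        zero_count=zero,
        zero_fraction=zero / len(results),
        most_stable_ids=tuple(results[i].id for i in order[:n_most_stable]),
        failed=len(library) - len(results),
    )


def length_mfe_correlation(lengths: np.ndarray, mfes: np.ndarray) -> float:
    """Pearson correlation between sequence length and MFE.

    Fixed-length libraries have zero length variance and no defined
    correlation; that case raises rather than returning NaN.
    """
    lengths = np.asarray(lengths, dtype=float)
    mfes = np.asarray(mfes, dtype=float)
    if lengths.size < 3:
        raise ValueError("need at least 3 (length, MFE) pairs")
    if np.ptp(lengths) == 0.0:
        raise ValueError(
            "length variance is zero (fixed-length library): length-MFE "
            "correlation is undefined"
        )
    if np.ptp(mfes) == 0.0:
        raise ValueError("MFE variance is zero: correlation is undefined")
    return float(stats.pearsonr(lengths, mfes).statistic)


def feature_mfe_correlations(features: pd.DataFrame, mfes: np.ndarray) -> pd.Series:
    """Pearson r between each feature column and MFE.

    Constant columns are flagged NaN (undefined), not fatal.
    """
    mfes = np.asarray(mfes, dtype=float)
    if len(features) != mfes.size:
        raise ValueError("feature rows and MFE values must align")
    if len(features) < 3:
        raise ValueError("need at least 3 sequences")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(mfes) == 0.0:
            out[col] = float("nan")
        else:
            out[col] = float(stats.pearsonr(x, mfes).statistic)
    return pd.Series(out, name="pearson_r_with_mfe")


def length_threshold_scan(
    n_min: int,
    n_max: int,
    backend: str | FoldingBackend = DEFAULT_BACKEND,
    sample_cap: int = 65_536,
    seed: int = 0,
    alphabet: Alphabet = RNA_ALPHABET,
) -> list[LengthScanRow]:
    """Count strictly-negative-MFE sequences per length.

    Lengths whose sequence space fits in ``sample_cap`` are enumerated
    exhaustively; larger spaces are probed with ``sample_cap`` seeded
    uniform draws (with-replacement draws de-duplicated, so the sampled
    total may fall slightly below the cap).  The ``arrangements`` column is
    always the exact 4**n.
    """
    if not (1 <= n_min <= n_max):
        raise ValueError("need 1 <= n_min <= n_max")
    bk = get_backend(backend)
    rng = np.random.default_rng(seed)
    rows: list[LengthScanRow] = []
    for n in range(n_min, n_max + 1):
        space = sequence_space_size(alphabet.size, n)
        if space <= sample_cap:
            seqs: list[AptamerSequence] = list(enumerate_all(n, alphabet, allow_large=True))
            exhaustive = True
        else:
            # dict preserves first-draw order, keeping output order seed-deterministic
            drawn = dict.fromkeys(
                generate_sequence(n, alphabet, rng, id=f"s{n}_{i}").residues
                for i in range(sample_cap)
            )
            seqs = [AptamerSequence(id=f"sample{n}_{i}", residues=s) for i, s in enumerate(drawn)]
            exhaustive = False
        nonzero = sum(1 for s in seqs if bk.fold(s).mfe < 0)
        rows.append(
            LengthScanRow(
                length=n,
                arrangements=space,
                sampled_total=len(seqs),
                nonzero_mfe_count=nonzero,
                exhaustive=exhaustive,
            )
        )
    return rows


def scan_to_frame(rows: list[LengthScanRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n": r.length,
                "arrangements": r.arrangements,
                "sampled_total": r.sampled_total,
                "nonzero_mfe_count": r.nonzero_mfe_count,
                "zeta": r.zeta,
                "exhaustive": r.exhaustive,
            }
            for r in rows
        ]
    )
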