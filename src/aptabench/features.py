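"""Per-sequence feature vectors and low-dimensional embedding.

The feature registry combines sequence composition (mono-, di- and
trinucleotide frequencies plus raw adjacency counts), structure-derived
descriptors (paired/unpaired counts, stem density, GC pair count within the
predicted structure), and simple thermodynamic/complexity descriptors
(Wallace-rule melting temperature, Shannon entropy of base usage, MFE,
length, GC/AU skew).  Feature vectors are z-score normalized per column
before PCA or t-SNE; zero-variance columns are dropped with a logged list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .composition import adjacent_counts, base_counts, kmer_frequencies, kmer_names
from .folding.backends import FoldResult
from .folding.structure import parse_dotbracket
from .generator import AptamerLibrary, AptamerSequence, RNA_ALPHABET

__all__ = [
    "FEATURE_REGISTRY_VERSION",
    "feature_names",
    "extract_features",
    "build_feature_matrix",
    "EmbeddingResult",
    "pca_embed",
    "tsne_embed",
]

logger = logging.getLogger(__name__)

FEATURE_REGISTRY_VERSION = "1"

_STRUCT_FEATURES = [
    "paired",
    "unpaired",
    "stem_density",
    "gc_skew",
    "au_skew",
    "tm_wallace",
    "shannon_entropy",
    "mfe",
    "length",
    "gc_pair_count",
]


def feature_names(alphabet=RNA_ALPHABET) -> list[str]:
    """Ordered, versioned registry of feature names (110 for A/U/G/C)."""
    names = [f"pct_{b}" for b in alphabet.symbols]
    names += [f"difreq_{d}" for d in kmer_names(2, alphabet) if len(d) == 2]
    names += [f"trifreq_{t}" for t in kmer_names(3, alphabet) if len(t) == 3]
    names += [f"adj_{d}" for d in kmer_names(2, alphabet) if len(d) == 2]
    names += _STRUCT_FEATURES
    return names


def _shannon_entropy(freqs: dict[str, float]) -> float:
    """Entropy of base usage in bits; 0 for homopolymers, 2 for uniform."""
    h = 0.0
    for pct in freqs.values():
        p = pct / 100.0
        if p > 0:
            h -= p * math.log2(p)
    return h


def _skew(x: int, y: int) -> float:
    """(x − y)/(x + y), defined as 0 when the denominator vanishes."""
    return 0.0 if x + y == 0 else (x - y) / (x + y)


def extract_features(seq: AptamerSequence, fold: FoldResult) -> dict[str, float]:
    """Deterministic named feature vector for one sequence and its fold.

    Melting temperature uses the Wallace rule 2(A+U) + 4(G+C) °C; stem
    density is paired/length; the GC pair count is the number of base pairs
    (i, j) in the predicted structure with {seq[i], seq[j]} = {G, C}.
    """
    if fold.sequence != seq.residues:
        raise ValueError(f"fold result {fold.id} does not match sequence {seq.id}")
    comp = base_counts(seq)
    counts = comp.counts
    _, kfreqs = kmer_frequencies(seq, kmax=min(3, seq.length))
    adj = adjacent_counts(seq).counts

    pairs = parse_dotbracket(fold.structure)
    paired = int(np.sum(pairs >= 0))
    gc_pairs = 0
    for i in range(len(pairs)):
        j = int(pairs[i])
        if j > i and {seq.residues[i], seq.residues[j]} == {"G", "C"}:
            gc_pairs += 1

    vec: dict[str, float] = {}
    for b in counts:
        vec[f"pct_{b}"] = comp.frequencies[b]
    for name in kmer_names(3):
        if len(name) == 2:
            vec[f"difreq_{name}"] = kfreqs.get(name, 0.0)
        elif len(name) == 3:
            vec[f"trifreq_{name}"] = kfreqs.get(name, 0.0)
    for d, c in adj.items():
        vec[f"adj_{d}"] = float(c)
    vec["paired"] = float(paired)
    vec["unpaired"] = float(seq.length - paired)
    vec["stem_density"] = paired / seq.length
    vec["gc_skew"] = _skew(counts["G"], counts["C"])
    vec["au_skew"] = _skew(counts["A"], counts["U"])
    vec["tm_wallace"] = 2.0 * (counts["A"] + counts["U"]) + 4.0 * (counts["G"] + counts["C"])
    vec["shannon_entropy"] = _shannon_entropy(comp.frequencies)
    vec["mfe"] = fold.mfe
    vec["length"] = float(seq.length)
    vec["gc_pair_count"] = float(gc_pairs)
    return vec


def build_feature_matrix(
    library: AptamerLibrary, fold_results: list[FoldResult]
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Raw and z-scored feature matrices for a library.

    Returns ``(raw, normalized, dropped)`` where ``normalized`` has mean 0
    and unit variance per retained column and ``dropped`` lists the
    zero-variance columns removed before normalization.
    """
    by_id = {r.id: r for r in fold_results}
    missing = [s.id for s in library if s.id not in by_id]
    if missing:
        raise ValueError(f"missing fold results for {len(missing)} sequences, e.g. {missing[:3]}")
    rows = [extract_features(s, by_id[s.id]) for s in library]
    raw = pd.DataFrame(rows, index=[s.id for s in library])
    raw = raw[feature_names()]  # enforce registry order
    std = raw.std(ddof=0)
    dropped = list(raw.columns[std == 0.0])
    if dropped:
        logger.info("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
    kept = raw.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all features are constant; nothing to embed")
    normalized = (kept - kept.mean()) / kept.std(ddof=0)
    return raw, normalized, dropped


@dataclass(frozen=True)
class EmbeddingResult:
    method: str  # "pca" | "tsne"
    coordinates: pd.DataFrame  # index = sequence ids, columns dim1, dim2, ...
    explained_variance_ratio: tuple[float, ...] | None = None
    params: dict | None = None


def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> EmbeddingResult:
    """Centered PCA with a deterministic sign convention.

    Each component's sign is fixed so that its largest-magnitude loading is
    positive, making the embedding reproducible across runs and backends.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA embedding needs at least 3 rows")
    if matrix.shape[1] < n_components:
        raise ValueError(
            f"PCA with {n_components} components needs at least that many columns, "
            f"got {matrix.shape[1]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(matrix.to_numpy(dtype=float))
    for c in range(n_components):
        loadings = pca.components_[c]
        if loadings[np.argmax(np.abs(loadings))] < 0:
            coords[:, c] *= -1.0
    frame = pd.DataFrame(
        coords, index=matrix.index, columns=[f"dim{i + 1}" for i in range(n_components)]
    )
    return EmbeddingResult(
        method="pca",
        coordinates=frame,
        explained_variance_ratio=tuple(float(v) for v in pca.explained_variance_ratio_),
        params={"n_components": n_components},
    )


def tsne_embed(
    matrix: pd.DataFrame, perplexity: float = 30.0, seed: int = 0
) -> EmbeddingResult:
    """2-D t-SNE; deterministic for a fixed seed within one library version."""
    n = matrix.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs more than 3 × perplexity rows: {n} rows vs perplexity "
            f"{perplexity} (bound {3 * perplexity:.0f})"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
    )
    coords = tsne.fit_transform(matrix.to_numpy(dtype=float))
    frame = pd.DataFrame(coords, index=matrix.index, columns=["dim1", "dim2"])
    return EmbeddingResult(
        method="tsne",
        coordinates=frame,
        params={"perplexity": perplexity, "seed": seed},
    )
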