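"""Folding backends: a named registry behind a single ``fold`` entry point.

* ``"turner"`` — the package's own Zuker-style MFE engine over the
  Turner-style nearest-neighbor tables (default; self-contained).
* ``"nussinov"`` — the simplified pair-maximization folder (pseudo-energy;
  for structural testing and CI).
* ``"viennarna"`` — thin wrapper around the ViennaRNA Python bindings when
  they are importable; raises an environment error naming ``"turner"`` as
  the fallback when they are not.

Aliases ``"vienna"`` (-> viennarna) and ``"builtin"`` (-> nussinov) are
accepted.  Every backend is deterministic: identical sequence and parameter
set give an identical result.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..generator import AptamerSequence
from . import nussinov, zuker
from .params import PARAMETER_SET
from .structure import validate_structure

__all__ = [
    "FoldResult",
    "FoldingBackend",
    "TurnerBackend",
    "NussinovBackend",
    "ViennaRNABackend",
    "BackendUnavailableError",
    "get_backend",
    "available_backends",
    "fold",
    "DEFAULT_BACKEND",
]

DEFAULT_BACKEND = "turner"


class BackendUnavailableError(RuntimeError):
    """The requested folding engine is not present in this environment."""


@dataclass(frozen=True)
class FoldResult:
    """One sequence's predicted structure: dot-bracket plus MFE (kcal/mol).

    MFE is always <= 0; MFE == 0 if and only if the structure is the open
    chain (all dots).
    """

    id: str
    sequence: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure and sequence lengths differ")
        if self.mfe > 0:
            raise ValueError("MFE must be <= 0")
        folded = any(ch != "." for ch in self.structure)
        if folded != (self.mfe < 0):
            raise ValueError("MFE = 0 must coincide with the open-chain structure")

    @property
    def folds(self) -> bool:
        return self.mfe < 0


class FoldingBackend:
    """Deterministic sequence -> FoldResult engine."""

    name: str = "abstract"
    parameter_set: str = ""

    def fold_string(self, sequence: str) -> tuple[str, float]:  # pragma: no cover
        raise NotImplementedError

    def fold(self, seq: AptamerSequence) -> FoldResult:
        structure, mfe = self.fold_string(seq.residues)
        # tiny positive scores are clamped to the open chain upstream; clamp
        # defensively here as well so the invariant holds for any backend
        if mfe >= 0:
            structure, mfe = "." * len(seq.residues), 0.0
        result = FoldResult(id=seq.id, sequence=seq.residues, structure=structure, mfe=mfe)
        validate_structure(result.sequence, result.structure)
        return result


class TurnerBackend(FoldingBackend):
    """Zuker-style MFE folding over the in-package nearest-neighbor tables."""

    name = "turner"
    parameter_set = PARAMETER_SET

    def fold_string(self, sequence: str) -> tuple[str, float]:
        return zuker.fold_mfe(sequence)


class NussinovBackend(FoldingBackend):
    """Simplified pair-maximization folding (model-specific pseudo-energy)."""

    name = "nussinov"
    parameter_set = "stack -1 / hairpin +3 pseudo-energy"

    def fold_string(self, sequence: str) -> tuple[str, float]:
        return nussinov.fold_simple(sequence)


class ViennaRNABackend(FoldingBackend):
    """Wrapper around the ViennaRNA bindings (optional dependency)."""

    name = "viennarna"

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore
        except ImportError as exc:
            raise BackendUnavailableError(
                "ViennaRNA Python bindings are not installed in this environment; "
                "use the self-contained 'turner' backend instead"
            ) from exc
        self._rna = RNA
        self.parameter_set = f"ViennaRNA {getattr(RNA, '__version__', '?')} defaults"

    def fold_string(self, sequence: str) -> tuple[str, float]:
        structure, mfe = self._rna.fold(sequence)
        return structure, float(mfe)


_REGISTRY: dict[str, type[FoldingBackend]] = {
    "turner": TurnerBackend,
    "nussinov": NussinovBackend,
    "viennarna": ViennaRNABackend,
}
_ALIASES = {"vienna": "viennarna", "builtin": "nussinov", "default": DEFAULT_BACKEND}


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def get_backend(name: str | FoldingBackend = DEFAULT_BACKEND) -> FoldingBackend:
    """Resolve a backend by name (or pass an instance through)."""
    if isinstance(name, FoldingBackend):
        return name
    key = _ALIASES.get(name.lower(), name.lower())
    if key not in _REGISTRY:
        raise ValueError(f"unknown backend {name!r}; choose from {available_backends()}")
    return _REGISTRY[key]()


def fold(seq: AptamerSequence, backend: str | FoldingBackend = DEFAULT_BACKEND) -> FoldResult:
    """Fold one sequence with the chosen backend."""
    return get_backend(backend).fold(seq)
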