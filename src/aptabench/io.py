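"""Readers/writers for FASTA, Vienna triplets and CSV tables, plus run
configuration and provenance.

FASTA is written unwrapped (one line per sequence); Vienna output is the
three-line ``>id`` / sequence / ``structure (MFE)`` convention with MFE in
parentheses to two decimals.  Every table writer can attach a provenance
sidecar (``<name>.meta.json``) carrying the tool version, seed, backend and
parameter set of the producing run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .generator import AptamerLibrary, AptamerSequence, RNA_ALPHABET
from .folding.backends import FoldResult

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "write_vienna",
    "write_csv",
    "write_provenance",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings of one run, serializable to JSON."""

    seed: int = 0
    count: int = 1100
    length_mode: str = "fixed"  # "fixed" | "range"
    length_n: int = 22
    length_j: int = 16
    length_k: int = 60
    backend: str = "turner"
    alpha: float = 0.05
    out_dir: str = "."
    log_level: str = "INFO"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def write_provenance(path: str | Path, **fields) -> None:
    """Write a ``<path>.meta.json`` sidecar with provenance metadata."""
    from . import __version__

    meta = {"tool": "aptabench", "version": __version__, **fields}
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(meta, indent=2) + "\n")


def read_fasta(
    path: str | Path,
    dna_to_rna: bool = False,
    deduplicate: bool = False,
) -> AptamerLibrary:
    """Read an RNA FASTA file into a library.

    Residues are uppercased; ``T`` is rejected with a conversion hint unless
    ``dna_to_rna`` converts it to ``U``.  Duplicate residue strings are an
    error unless ``deduplicate`` drops later copies (logged).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    sequences: list[AptamerSequence] = []
    seen: dict[str, str] = {}
    for idx, rec in enumerate(records, start=1):
        residues = str(rec.seq).upper()
        if not residues:
            raise ValueError(f"{path}: record {idx} ({rec.id!r}) is empty")
        if "T" in residues:
            if dna_to_rna:
                residues = residues.replace("T", "U")
            else:
                raise ValueError(
                    f"{path}: record {idx} ({rec.id!r}) contains 'T'; this is an "
                    "RNA toolkit — pass dna_to_rna=True (--dna-to-rna) to convert"
                )
        bad = set(residues) - set(RNA_ALPHABET.symbols)
        if bad:
            raise ValueError(
                f"{path}: record {idx} ({rec.id!r}) has invalid residue(s) "
                f"{sorted(bad)}; expected A/C/G/U"
            )
        if residues in seen:
            if deduplicate:
                logger.warning(
                    "%s: record %r duplicates %r; dropped", path, rec.id, seen[residues]
                )
                continue
            raise ValueError(
                f"{path}: record {idx} ({rec.id!r}) duplicates {seen[residues]!r}; "
                "pass deduplicate=True (--deduplicate) to drop copies"
            )
        seen[residues] = rec.id
        sequences.append(AptamerSequence(id=rec.id, residues=residues))
    return AptamerLibrary(sequences=sequences, config=None, source=str(path))


def write_fasta(library: AptamerLibrary, path: str | Path) -> None:
    """Unwrapped FASTA: ``>id length=n`` header, single-line residues."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in library:
            fh.write(f">{seq.id} length={seq.length}\n{seq.residues}\n")


def write_vienna(results: list[FoldResult], path: str | Path) -> None:
    """Vienna triplets: ``>id`` / sequence / ``structure (MFE)`` (2 decimals)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in results:
            fh.write(f">{r.id}\n{r.sequence}\n{r.structure} ({r.mfe:.2f})\n")


def write_csv(table: pd.DataFrame, path: str | Path, index: bool = False, **provenance) -> None:
    """UTF-8 CSV with a header row; provenance goes to a JSON sidecar."""
    path = Path(path)
    table.to_csv(path, index=index)
    if provenance:
        write_provenance(path, **provenance)
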