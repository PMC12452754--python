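"""Shared fixtures: generated libraries and fold results, built once."""

from __future__ import annotations

import numpy as np
import pytest

from aptabench.folding import fold_library
from aptabench.generator import (
    AptamerSequence,
    GeneratorConfig,
    LengthSpec,
    generate_library,
)


@pytest.fixture(scope="session")
def fixed_library():
    """1100 unique 22-nt sequences, seed 0 (the fixed-length study library)."""
    return generate_library(
        GeneratorConfig(seed=0, count=1100, length_spec=LengthSpec.fixed(22))
    )


@pytest.fixture(scope="session")
def fixed_folds(fixed_library):
    return fold_library(fixed_library, "turner")


@pytest.fixture(scope="session")
def random_library():
    """5000 unique sequences with lengths uniform on [16, 60] (scaled study)."""
    return generate_library(
        GeneratorConfig(seed=1, count=5000, length_spec=LengthSpec.uniform_range(16, 60))
    )


@pytest.fixture(scope="session")
def random_folds(random_library):
    return fold_library(random_library, "turner")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


@pytest.fixture()
def make_seq():
    def _make(residues: str, id: str = "seq") -> AptamerSequence:
        return AptamerSequence(id=id, residues=residues)

    return _make
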