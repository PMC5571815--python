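from __future__ import annotations

import numpy as np
import pytest

from mitoscan.data import (
    load_cds_indels,
    load_lur_band_lengths,
    load_reference_annotation,
    load_reference_codon_counts,
)
from mitoscan.simulate import generate_genome, venerid_like


@pytest.fixture(scope="session")
def ref_annotation():
    return load_reference_annotation()


@pytest.fixture(scope="session")
def ref_codon_counts():
    return load_reference_codon_counts()


@pytest.fixture(scope="session")
def lur_bands():
    return load_lur_band_lengths()


@pytest.fixture(scope="session")
def cds_indels():
    return load_cds_indels()


@pytest.fixture(scope="session")
def sim_genome():
    """Default venerid-like synthetic genome with its truth set (seed 42)."""
    return generate_genome(venerid_like(seed=42))


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))
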