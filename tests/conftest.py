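"""Shared fixtures: deterministic RNG helpers and small simulated datasets."""

import numpy as np
import pytest

from renseqtk.records import ReadRecord, SequenceSet
from renseqtk.simulate import ERROR_FREE, SimConfig, simulate_reference

BASES = "ACGT"


def random_dna(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genes():
    """Six NLR-like genes (3 families x 2 paralogs), ~2 kb each."""
    cfg = SimConfig(seed=101, n_families=3, paralogs_per_family=2,
                    gene_length_range=(1800, 2200))
    genes, annotations = simulate_reference(cfg)
    return genes, annotations


def make_set(seqs, prefix="s"):
    return SequenceSet.from_records(
        [ReadRecord(f"{prefix}{i}", s) for i, s in enumerate(seqs, 1)]
    )
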