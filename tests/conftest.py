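import numpy as np
import pytest

from hapgy import synthetic_data as syn
from hapgy.io_genotypes import MISSING, GenotypeMatrix


@pytest.fixture(scope="session")
def bundle():
    return syn.fixture_suite(seed=0)


@pytest.fixture(scope="session")
def sim_small():
    """Small forward-simulated cohort shared across test modules."""
    spec = syn.SimulationSpec(
        n_lines=200,
        n_founders=16,
        chromosomes=[syn.ChromosomeSpec(50_000_000, 120) for _ in range(2)],
        missing_rate=0.05,
        seed=42,
    )
    g, anc = syn.simulate_genotypes(spec)
    return spec, g, anc


def toy_matrix(calls, chrom=None, pos=None, alleles=None):
    """GenotypeMatrix from a plain call array with synthetic ids."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        line_ids=[f"L{i}" for i in range(n)],
        marker_ids=[f"M{j}" for j in range(m)],
        chrom=chrom if chrom is not None else ["chr1"] * m,
        pos_bp=pos if pos is not None else (np.arange(m) + 1) * 1000,
        calls=calls,
        alleles=alleles,
    )


@pytest.fixture
def toy():
    return toy_matrix
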