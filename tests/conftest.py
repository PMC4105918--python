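import numpy as np
import pytest

from snppanel.datatypes import GenotypeDataset
from snppanel.simulate import SimulationConfig, simulate_environment, simulate_genotypes


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale riverscape used across unit tests: 3 regions x 4
    populations x 20 individuals, 80 loci of which 4 carry clines."""
    return SimulationConfig(
        n_regions=3,
        pops_per_region=4,
        inds_per_pop=20,
        n_loci=80,
        n_candidates=4,
        cline_beta=1.5,
        missing_rate=0.01,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_env(small_config):
    return simulate_environment(small_config)


@pytest.fixture(scope="session")
def small_data(small_config, small_env):
    return simulate_genotypes(small_config, small_env)


@pytest.fixture(scope="session")
def small_dataset(small_data):
    return small_data[0]


@pytest.fixture(scope="session")
def small_truth(small_data):
    return small_data[1]


def toy_dataset(calls, pops=None, locus_ids=None):
    """Hand-built dataset from a calls matrix (rows: individuals)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pops = pops or [f"P{i // max(1, n // 2) + 1}" for i in range(n)]
    return GenotypeDataset(
        individual_ids=[f"ind{i + 1}" for i in range(n)],
        population_labels=list(pops),
        locus_ids=locus_ids or [f"L{j + 1}" for j in range(m)],
        calls=calls,
    )
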