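import numpy as np
import pytest

from darkdiv import OccurrenceMatrix, PipelineConfig, run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_occurrence(n_sites, n_species, seed, density=0.3):
    """Random binary matrix guaranteed to have no all-zero species column."""
    gen = np.random.default_rng(seed)
    values = (gen.random((n_sites, n_species)) < density).astype(np.int8)
    empty = values.sum(axis=0) == 0
    values[gen.integers(n_sites, size=int(empty.sum())), np.where(empty)[0]] = 1
    sites = tuple(f"s{i}" for i in range(n_sites))
    species = tuple(f"sp{j}" for j in range(n_species))
    return OccurrenceMatrix(sites, species, values)


@pytest.fixture
def small_occ():
    # 4 sites x 3 species worked example: A at {1,2}, B at {2,3}, C at {3,4}
    values = np.array([
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 1],
        [0, 0, 1],
    ])
    return OccurrenceMatrix(("s1", "s2", "s3", "s4"), ("A", "B", "C"), values)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_result(default_config):
    """The default synthetic scenario run once per session (seed 1)."""
    return run_pipeline(default_config)
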