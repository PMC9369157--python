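import numpy as np
import pytest
from hypothesis import settings

from seedallometry import ComponentReferenceMatrix, GeneratorConfig, simulate_cohort

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref():
    return ComponentReferenceMatrix()


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 8-accession x 5-seed cohort in the default elemental mode."""
    cfg = GeneratorConfig(n_seeds_per_accession=5, rng_seed=7)
    seeds, matrix, ann = simulate_cohort(cfg)
    return cfg, seeds, matrix, ann


@pytest.fixture(scope="session")
def biochem_cohort():
    """Deterministic cohort in biochemical mode: exact forward-model elemental data."""
    cfg = GeneratorConfig(n_seeds_per_accession=5, rng_seed=11, mode="biochemical")
    seeds, matrix, ann = simulate_cohort(cfg)
    return cfg, seeds, matrix, ann


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
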