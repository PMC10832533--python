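import numpy as np
import pytest

from plasmidtx.synthetic import (
    CountDesign, GenParams, generate_plasmid, simulate_counts, simulate_coverage,
)


@pytest.fixture(scope="session")
def default_fixture():
    """Seeded 16-gene plasmid with planted regulatory truth."""
    params = GenParams(seed=1, n_genes=16, genome_length=26000)
    bundle, truth = generate_plasmid(params)
    return params, bundle, truth


@pytest.fixture(scope="session")
def covered_fixture(default_fixture):
    params, bundle, truth = default_fixture
    cov, stats = simulate_coverage(bundle, truth, seed=2)
    return bundle, truth, cov, stats


@pytest.fixture(scope="session")
def default_counts():
    counts, deg_truth = simulate_counts(CountDesign(seed=5))
    return counts, deg_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
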