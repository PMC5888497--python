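import numpy as np
import pytest

from guidemeth.simulate import SyntheticGenomeSpec, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A 1 Mb synthetic nine-group study shared by the unit tests."""
    spec = SyntheticGenomeSpec(genome_length=1_000_000, rng_seed=7)
    return simulate_study(genome_spec=spec, seed=7, n_planted_offtargets=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
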