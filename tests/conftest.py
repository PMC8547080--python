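import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from omegatrait import simulate as sim  # noqa: E402
from omegatrait.trees_io import brownian_covariance  # noqa: E402


@pytest.fixture(scope="session")
def fixture_tree():
    return sim.fixture_tree()


@pytest.fixture(scope="session")
def fixture_phenotypes():
    return sim.fixture_phenotypes()


@pytest.fixture(scope="session")
def fixture_covariance(fixture_tree):
    return brownian_covariance(fixture_tree)


@pytest.fixture(scope="session")
def small_tree():
    """6-tip Yule tree in expected-substitutions-per-codon units."""
    return sim.simulate_tree(6, seed=3, depth=0.5)


@pytest.fixture(scope="session")
def small_alignment(small_tree):
    aln, _ = sim.simulate_codon_alignment(small_tree, 0.3, n_codons=200, seed=4)
    return aln


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
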