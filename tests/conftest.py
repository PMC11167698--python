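import numpy as np
import pytest

from chef.structure_coherence import fingerprint_dataset
from chef.synthetic_fixtures import (
    FixtureSpec,
    build_ground_truth_dataset,
    generate_families,
    generate_mock_patents,
    make_mock_backend,
)


@pytest.fixture(scope="session")
def small_spec():
    """Noise-free mini corpus: 4 scaffold families of 6 molecules."""
    return FixtureSpec(n_families=4, family_size=6, label_noise=0.0, seed=7)


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return generate_families(small_spec)


@pytest.fixture(scope="session")
def small_corpus(small_spec, small_fixture):
    return generate_mock_patents(small_fixture, small_spec)


@pytest.fixture(scope="session")
def small_dataset(small_fixture):
    return build_ground_truth_dataset(small_fixture)


@pytest.fixture(scope="session")
def mock_backend(small_spec):
    return make_mock_backend(small_spec)


@pytest.fixture(scope="session")
def default_spec():
    """The benchmark study conditions: 10 families x 20, 5% noise, seed 42."""
    return FixtureSpec()


@pytest.fixture(scope="session")
def default_fixture(default_spec):
    return generate_families(default_spec)


@pytest.fixture(scope="session")
def default_dataset(default_fixture):
    return build_ground_truth_dataset(default_fixture)


@pytest.fixture(scope="session")
def default_fps(default_dataset):
    return fingerprint_dataset(default_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
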