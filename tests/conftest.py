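import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import litrec as lr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> lr.SyntheticSpec:
    """A small planted-structure corpus spec for fast unit tests."""
    return lr.SyntheticSpec(
        n_authors=12,
        n_docs=50,
        n_topics=4,
        entities_per_topic=8,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec) -> lr.CorpusBundle:
    return lr.generate_corpus(small_spec)


@pytest.fixture(scope="session")
def default_corpus() -> lr.CorpusBundle:
    """A corpus at the generator's default study conditions."""
    return lr.generate_corpus(lr.SyntheticSpec(seed=2024))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(97531)
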