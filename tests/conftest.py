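import random

import pytest
from hypothesis import HealthCheck, settings

from erd.fold_engine import ToyEngine, ViennaEngine
from erd.pools import build_pools, generate_synthetic_corpus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_engine():
    return ToyEngine()


@pytest.fixture(scope="session")
def vienna_engine():
    return ViennaEngine()


@pytest.fixture(scope="session")
def corpus():
    """Synthetic stand-in for a natural-sequence corpus."""
    return generate_synthetic_corpus(200, (50, 150), random.Random(7))


@pytest.fixture(scope="session")
def vienna_pool(corpus, vienna_engine):
    return build_pools(corpus, vienna_engine)


@pytest.fixture(scope="session")
def toy_pool(corpus, toy_engine):
    return build_pools(corpus[:80], toy_engine)
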