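import random

import pytest
from hypothesis import settings

import rgrkit as rk

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return rk.load_registry()


@pytest.fixture(scope="session")
def bundle():
    """Deterministic synthetic fixtures: spacers, vectors, promoter."""
    return rk.generate_fixtures(seed=1)


@pytest.fixture()
def rng():
    return random.Random(1234)


@pytest.fixture(scope="session")
def two_rgr_array(registry, bundle):
    """A Cas12a + Cas9 two-guide multiplex array (one guide per system)."""
    lb = next(s for s in bundle.spacers if s.cas == "lbcas12a")
    sp = next(s for s in bundle.spacers if s.cas == "spcas9")
    return rk.build_array([lb, sp], registry)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))
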