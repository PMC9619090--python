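import numpy as np
import pytest

from radvasc import phantom, training


@pytest.fixture(scope="session")
def default_case():
    """One default phantom case (seed 1), shared read-only across tests."""
    return phantom.generate_case(phantom.PhantomParams(seed=1))


@pytest.fixture(scope="session")
def case_bank():
    """Lazily generated, cached phantom cases keyed by seed."""
    cache = {}

    def get(seed, **overrides):
        key = (seed, repr(sorted(overrides.items())))
        if key not in cache:
            cache[key] = phantom.generate_case(phantom.PhantomParams(seed=seed, **overrides))
        return cache[key]

    return get


@pytest.fixture(scope="session")
def models():
    """The standard trained trio: patch dictionary, logistic classifier, texture model."""
    return training.default_models(0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
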