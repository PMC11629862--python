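import pytest

from replicluster.synth import carbon_fixture, random_linlog


@pytest.fixture(scope="session")
def carbon():
    return carbon_fixture()


@pytest.fixture(scope="session")
def small_models():
    """A batch of small random linlog models for property checks."""
    return [random_linlog(m=4 + s % 3, r=7 + s % 4, seed=s) for s in range(5)]
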