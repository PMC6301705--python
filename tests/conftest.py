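import pytest

from oxidimer.io import load_fixtures
from oxidimer.synthetic import SynthConfig, generate_registry


@pytest.fixture(scope="session")
def fixtures():
    """Packaged transcriptions of the printed reference tables."""
    return load_fixtures()


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=20_240_101)


@pytest.fixture(scope="session")
def synth_registry(synth_config):
    """A Hess-consistent synthetic species registry (seeded)."""
    return generate_registry(synth_config)
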