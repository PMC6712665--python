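import pytest

from emgekit.simulate import SimConfig, generate_community


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def community(default_config):
    return generate_community(default_config)
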