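import pytest

from dbscal import GeneratorConfig, builtin_device_profiles


@pytest.fixture
def config():
    """Default study-condition generator configuration."""
    return GeneratorConfig()


@pytest.fixture
def noiseless(config):
    """Same configuration with all noise off: closed-form outputs."""
    return config.noiseless()


@pytest.fixture
def unit_response():
    """Noiseless config with IS normalisation 1, so ratio = kappa*C*V*EE*ME."""
    return GeneratorConfig(
        response_factor={"peth_16_0_18_1": 1.0, "peth_16_0_18_2": 1.0},
        is_amount=1.0,
        is_response_factor=1.0,
    ).noiseless()


@pytest.fixture
def profiles():
    return builtin_device_profiles()
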