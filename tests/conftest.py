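import pytest
from hypothesis import HealthCheck, settings

from medcrosswalk.fixtures import figures34
from medcrosswalk.synthgen import SynthConfig, generate_world

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig34():
    """The warfarin worked-example micro-world."""
    return figures34()


@pytest.fixture(scope="session")
def noiseless_world():
    """Small noiseless world: every crosswalk should be the identity."""
    return generate_world(SynthConfig.noiseless(n_drugs=40, n_patients=300, seed=11))


@pytest.fixture(scope="session")
def noisy_world():
    """Small world with every imperfection switched on at its default rate."""
    return generate_world(SynthConfig(n_drugs=150, n_patients=400, seed=23))
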