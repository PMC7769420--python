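import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_fixture():
    """One default synthetic experiment shared by the slower tests."""
    from srnadig.synth import SynthConfig, generate

    return generate(SynthConfig(seed=1))
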