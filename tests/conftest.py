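import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    from msfd9 import load_catalog

    return load_catalog("builtin")


@pytest.fixture(scope="session")
def basin_polygon():
    from msfd9 import fixture_polygon

    return fixture_polygon("elongated_basin")
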