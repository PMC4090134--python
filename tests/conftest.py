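import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from wallstress import TubeGeometry, get_material

#: systolic pressure, N/mm^2 (120 mmHg)
P_SYS = 0.016


@pytest.fixture(scope="session")
def rv():
    return get_material("RV")


@pytest.fixture(scope="session")
def p1():
    return get_material("P1")


@pytest.fixture(scope="session")
def p2():
    return get_material("P2")


@pytest.fixture(scope="session")
def imaged_tube():
    """Deformed-configuration radii of the benchmark tube (mm)."""
    return TubeGeometry(14.8, 16.1)
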