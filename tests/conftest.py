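import pytest
from hypothesis import HealthCheck, settings

from liftrisk import DamageParams, LiftTask

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params() -> DamageParams:
    """Default S-N parameters."""
    return DamageParams()


@pytest.fixture
def scenario_task() -> LiftTask:
    """50 lb (22.7 kg) object at 70 cm, 1000 lifts."""
    return LiftTask(mass=22.7, distance=0.70, repetitions=1000)
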