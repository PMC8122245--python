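import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from emophys import EmotionStudy, SimConfig, simulate_study  # noqa: E402


@pytest.fixture(scope="session")
def tiny_study():
    """Two participants, default planted structure — fast but complete."""
    return simulate_study(SimConfig(n_participants=2, seed=7))


@pytest.fixture(scope="session")
def tiny_model(tiny_study):
    return EmotionStudy.from_study(tiny_study)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
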