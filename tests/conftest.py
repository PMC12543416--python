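import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cagetrack.pipeline import PipelineConfig
from cagetrack.simulate import SimScenario, simulate_streams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def corrupted_session():
    """One 30 min session with realistic corruption, shared across tests:
    5% missed detections, 2 px jitter, 0.2 s camera latency, occasional
    spurious boxes."""
    scenario = SimScenario(
        seed=42,
        duration_s=1800.0,
        miss_prob=0.05,
        jitter_sd_px=2.0,
        latency_offset_s=0.2,
        false_box_rate=0.01,
    )
    truth, front, side = simulate_streams(scenario)
    return scenario, truth, front, side


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()
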