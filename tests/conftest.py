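import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    from writetrace.synthetic import SessionConfig

    return SessionConfig(n_participants=3, sentences_per_text=6, seed=17)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Events, fixations and ground truth for a 3-participant study."""
    from writetrace.synthetic import generate_study

    return generate_study(small_config)
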