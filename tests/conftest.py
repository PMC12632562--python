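import pytest
from hypothesis import settings

from splicepharm.simulate import SimConfig

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_cfg():
    """A fast, fully deterministic simulation configuration."""
    return SimConfig(n_events=40, read_depth=100.0, seed=11)
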