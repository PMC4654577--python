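import numpy as np
import pytest

from triadstress.ppg import SegmentMap
from triadstress.synthetic import SimulationConfig, SubjectPhysio


@pytest.fixture
def segments() -> SegmentMap:
    return SegmentMap(video=(0.0, 200.0), conversation=(205.0, 805.0))


@pytest.fixture
def flat_physio() -> SubjectPhysio:
    """No reactivity: same rate and amplitude in every state."""
    return SubjectPhysio("S", 72.0, 72.0, 72.0, 1.0, 1.0, 1.0)


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_triads=2, n_study1=1, seed=7,
                            emulate_missing_aa=False,
                            emulate_missing_post=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
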