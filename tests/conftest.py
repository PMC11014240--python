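import numpy as np
import pytest

from cwmsim import SimulationConfig, build_long_sequence
from cwmsim.rng import child_rng


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def timing_rng():
    return child_rng(1, "timing")


@pytest.fixture
def velocity_rng():
    return child_rng(1, "velocity")


@pytest.fixture(scope="session")
def long_trace():
    """60 s displacement recording shared by the spectral/sequence tests."""
    cfg = SimulationConfig(seed=7, duration=60.0)
    return build_long_sequence(cfg)


@pytest.fixture(scope="session")
def regular_trace():
    """Long recording with narrowed beat-length spread.

    Beat-to-beat variability smears the spectral fundamental over several
    FFT bins; the peak-tracking checks use this low-variability run so the
    +/- 1 bin assertion is meaningful.
    """
    cfg = SimulationConfig(seed=7, duration=60.0,
                           timing={"cycle_len": (0.80, 0.84)},
                           hrv_sigma_range=(0.0, 0.0))
    return build_long_sequence(cfg)


@pytest.fixture(scope="session")
def short_trace():
    """8 s recording used by the end-to-end checks."""
    cfg = SimulationConfig(seed=3, duration=8.0)
    return build_long_sequence(cfg)
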