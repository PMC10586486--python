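import numpy as np
import pytest

from petvt import FrameSchedule, SimulationConfig, simulate_aif
from petvt.simulate import derive_micro_params


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def aif(config):
    """Default noise-free input function on the 1-s fine grid."""
    return simulate_aif(config)


@pytest.fixture(scope="session")
def mid_params(config):
    """Mid-range 2TCM parameters reaching V_T = 4 with the default kinetics."""
    return derive_micro_params(4.0, config.k1, config.k2, config.k4, vb=config.vb)


def draw_params(rng):
    """Admissible random 2TCM parameter draw for estimator sweeps.

    Ranges give reversible kinetics with uptake fast enough to peak within
    the scan and washout representative of the simulated tracer.
    """
    k1 = rng.uniform(0.2, 0.8)
    k2 = rng.uniform(0.3, 0.8)
    k3 = rng.uniform(0.01, 0.25)
    k4 = rng.uniform(0.04, 0.15)
    from petvt import TwoTCMParams
    return TwoTCMParams(k1=k1, k2=k2, k3=k3, k4=k4, vb=0.04)
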