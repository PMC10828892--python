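import numpy as np
import pytest

from mcftwin.geometry import generate_fiber_layout, sample_transmissivity


@pytest.fixture(scope="session")
def seven_core_layout():
    """One center core plus its six hexagonal neighbors, pitch 8."""
    return generate_fiber_layout((48, 48), pitch_px=8.0, jitter_std_px=0.0,
                                 bundle_radius_px=8.5, seed=0)


@pytest.fixture(scope="session")
def medium_layout():
    """~150-core jittered layout on a 128 px canvas, pitch 8."""
    return generate_fiber_layout((128, 128), pitch_px=8.0, jitter_std_px=0.8,
                                 bundle_radius_px=56.0, seed=1)


@pytest.fixture(scope="session")
def medium_tmap(medium_layout):
    return sample_transmissivity(medium_layout, mean=0.8, std=0.15, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
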