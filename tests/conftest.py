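import numpy as np
import pytest

from posturedyn import GaitSpec, SwaySpec, gen_gait, gen_sway
from posturedyn.benchmarks import lorenz_trajectory


@pytest.fixture(scope="session")
def lorenz_x():
    """Lorenz x-coordinate, standard parameters, dt=0.01, 100 time units."""
    return lorenz_trajectory(duration=100.0, dt=0.01)


@pytest.fixture(scope="session")
def small_gait():
    """A 60-stride noisy walking trial with its ground truth."""
    return gen_gait(GaitSpec(n_strides=60, seed=11))


@pytest.fixture(scope="session")
def periodic_gait():
    """Strictly periodic gait at a sampling-commensurate cadence
    (integer samples per step), so sampled cycles repeat exactly."""
    spec = GaitSpec(n_strides=60, cadence=112.5, step_time_sd=0.0,
                    step_width_sd=0.0, noise_sd_frac=0.0, chaos_gain=0.0,
                    seed=0)
    return gen_gait(spec)


@pytest.fixture()
def brownian_sway():
    return gen_sway(SwaySpec(d_ml=2.0, d_ap=1.0, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
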