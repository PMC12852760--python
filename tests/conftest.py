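import numpy as np
import pytest

import raffsim as rs


@pytest.fixture(scope="session")
def healthy_system():
    return rs.build_two_pool_system("Fn1", "healthy")


@pytest.fixture(scope="session")
def tl1_packet():
    return rs.make_raff2_packet(625.0, 1.0)


@pytest.fixture(scope="session")
def tl1_fit(healthy_system, tl1_packet):
    cp, cm = rs.simulate_decay_curves(healthy_system, tl1_packet)
    return rs.fit_ss_model(cp, cm)


@pytest.fixture
def small_phantom_spec():
    """Downscaled phantom for fast per-pixel fitting tests."""
    return rs.PhantomSpec(
        shape=(48, 48),
        inner_radius=9.0,
        outer_radius=17.0,
        region_params=rs.default_region_params(1.123),
        noise_sigma=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def echo_times():
    return np.array([0.0, 18.2e-3, 36.4e-3, 72.8e-3])
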