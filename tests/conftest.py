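import numpy as np
import pytest

import cbct4d as c


@pytest.fixture(scope="session")
def default_phantom():
    return c.build_default_phantom()


@pytest.fixture(scope="session")
def water_cylinder():
    """Uniform water cylinder, radius 8 cm, the analytic workhorse."""
    return c.DigitalPhantom(
        housing_radius=8.0,
        modules=[c.PhantomModule("uniform", (-6.0, 6.0))])


@pytest.fixture(scope="session")
def small_detector():
    return c.DetectorGeometry(n_u=160, n_v=32, du=0.2, dv=0.3)


@pytest.fixture(scope="session")
def water_cone_scan(water_cylinder, small_detector):
    """Static cone-beam scan of the water cylinder (90 views)."""
    proto = c.AcquisitionProtocol(gantry_speed=6.0, frame_rate=1.5,
                                  detector=small_detector)
    return c.forward_project(water_cylinder, None, proto, sampling_step=0.1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160729)
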