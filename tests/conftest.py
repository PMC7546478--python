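import numpy as np
import pytest

from magbrachy.phantoms import PhantomSpec, make_lung_cube
from magbrachy.sources import PointElectronSource
from magbrachy.transport import FieldSpec, TransportParams, run_histories


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201009)


@pytest.fixture(scope="session")
def lung_cube():
    """1 cm³ lung cube at 0.1 mm spacing (fast test resolution)."""
    return make_lung_cube(PhantomSpec(spacing_mm=(0.1, 0.1, 0.1)))


@pytest.fixture(scope="session")
def fast_params():
    return TransportParams(max_step=0.5)


@pytest.fixture(scope="session")
def mono_b0(lung_cube, fast_params):
    """Shared 432 keV, B = 0 run for engine-invariant checks."""
    src = PointElectronSource([0.0, 0.0, 0.0], energy=0.432)
    return run_histories(src, lung_cube, FieldSpec((0, 0, 0)),
                         fast_params, 120_000, n_batches=10, seed=42)


@pytest.fixture(scope="session")
def mono_b3(lung_cube, fast_params):
    src = PointElectronSource([0.0, 0.0, 0.0], energy=0.432)
    return run_histories(src, lung_cube, FieldSpec((0, 0, 3.0)),
                         fast_params, 120_000, n_batches=10, seed=42)
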