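import numpy as np
import pytest

from nrcsim import (BoundaryEnvironment, ConstructGeometry, REFERENCE_PARAMS,
                    SeedingSpec)
from nrcsim.units import CELLS_ML_TO_M3, HOUR


@pytest.fixture(scope="session")
def params():
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def impermeable_geometry():
    return ConstructGeometry(Lp=0.0)


@pytest.fixture(scope="session")
def porous_geometry():
    """Fully porous sheath: overlapping spheres, eps = 0.8, T = 0.25 mm."""
    return ConstructGeometry(Lp=7.5e-3, epsilon=0.8, structure="spheres",
                             T=2.5e-4)


@pytest.fixture(scope="session")
def environment():
    return BoundaryEnvironment()


@pytest.fixture(scope="session")
def baseline_seeding():
    return SeedingSpec.uniform(1.78e8 * CELLS_ML_TO_M3)


@pytest.fixture(scope="session")
def baseline_1d_run(impermeable_geometry, environment, baseline_seeding):
    """24 h impermeable baseline on the 1D fast path (shared, read-only)."""
    from nrcsim import simulate_axial_1d
    return simulate_axial_1d(impermeable_geometry, environment,
                             baseline_seeding, t_end=24 * HOUR, nz=99)


@pytest.fixture(scope="session")
def porous_2d_run(porous_geometry, environment, baseline_seeding):
    """24 h fully porous run on a coarse axisymmetric mesh (shared)."""
    from nrcsim import simulate
    return simulate(porous_geometry, environment, baseline_seeding,
                    t_end=24 * HOUR,
                    output_times=[0, 0.5 * HOUR, 1 * HOUR, 12 * HOUR,
                                  24 * HOUR],
                    nz=45, nr_core=5, nr_sheath=3)
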