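import numpy as np
import pytest

import rotasym as rs


@pytest.fixture(scope="session")
def c17_ring_map() -> rs.DensityMap:
    """Noiseless 17-subunit ring phantom at the default detection geometry."""
    spec = rs.RingPhantomSpec(n_subunits=17, ring_radius=150.0, subunit_sigma=12.0)
    return rs.make_ring_phantom(spec, (128, 128, 128), 4.0)


@pytest.fixture(scope="session")
def small_c17_map() -> rs.DensityMap:
    """Smaller C17 ring for the slower whole-map operations (lathe, rotate)."""
    spec = rs.RingPhantomSpec(n_subunits=17, ring_radius=90.0, subunit_sigma=8.0)
    return rs.make_ring_phantom(spec, (64, 64, 64), 4.0)


@pytest.fixture(scope="session")
def beta_collar_map() -> rs.DensityMap:
    """62 Å cylindrical-shell phantom (the widened FliF β-collar geometry)."""
    return rs.make_cylinder_phantom(62.0, 60.0, 6.0, (128, 128, 128), 2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
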