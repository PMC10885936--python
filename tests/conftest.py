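import numpy as np
import pytest

from spinenorm.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless 3-station phantom with unit gains."""
    spec = PhantomSpec(n_stations=3, slices_per_station=8, matrix=32,
                       canal_radius_mm=6.0, cord_radius_mm=4.6,
                       noise_sigma=0.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def gained_phantom():
    """Noiseless 3-station phantom with known station gains (1, 1.3, 0.8)."""
    spec = PhantomSpec(n_stations=3, slices_per_station=8, matrix=32,
                       canal_radius_mm=6.0, cord_radius_mm=4.6,
                       station_gains=(1.0, 1.3, 0.8), noise_sigma=0.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
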