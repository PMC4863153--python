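"""Shared fixtures: expensive Monte Carlo runs are session-scoped so the
whole suite pays for each simulation once."""

import logging

import numpy as np
import pytest

from iondose.fixtures import water_phantom
from iondose.stopping import PROTON
from iondose.transport import BeamSpec, TransportConfig, run_simulation

logging.getLogger("iondose").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def proton_water_grid():
    """150 MeV proton pencil beam in a 200 x 40 x 40 mm water phantom,
    full physics, 10^4 primaries."""
    phantom = water_phantom(length_mm=200.0, cross_section_mm=40.0,
                            spacing_mm=1.0)
    beam = BeamSpec(PROTON, 150.0, n_primaries=10_000, energy_sigma=0.3,
                    spot_sigma_x=2.0, spot_sigma_y=2.0,
                    position=(20.0, 20.0, 0.0))
    config = TransportConfig(rng_seed=42)
    return run_simulation(beam, phantom, config)


@pytest.fixture(scope="session")
def proton_water_grid_analytic():
    """Same beam with straggling/MCS off and pure attenuation; used for
    survival and geometry checks that have closed-form references."""
    phantom = water_phantom(length_mm=200.0, cross_section_mm=20.0,
                            spacing_mm=1.0)
    beam = BeamSpec(PROTON, 150.0, n_primaries=10_000,
                    position=(10.0, 10.0, 0.0))
    config = TransportConfig(rng_seed=7, straggling_model="none",
                             mcs_model="none", nuclear_model="attenuation")
    return run_simulation(beam, phantom, config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
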