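"""Shared fixtures.

The Monte Carlo fixtures are session-scoped and deliberately sized so the
whole suite runs on one CPU in a few minutes: quantile estimates at these
photon counts are stable to well under a percent, far below the physical
tolerances they are compared against.
"""

import numpy as np
import pytest

from sfdikit import mc
from sfdikit.inversion import ForwardModelSettings, build_lut
from sfdikit.optics import apple_properties, load_apple_table


@pytest.fixture(scope="session")
def apple_table():
    return load_apple_table()


@pytest.fixture(scope="session")
def default_lut():
    return build_lut(ForwardModelSettings())


@pytest.fixture(scope="session")
def mc_550():
    """Transport run at the 550 nm apple properties (1e5 photons)."""
    cfg = mc.TransportConfig(
        medium=apple_properties(550), n_photons=100_000, seed=mc.DEFAULT_SEED
    )
    return mc.run_transport(cfg)


@pytest.fixture(scope="session")
def depth_sweep(apple_table):
    """Planar sampling-depth quantiles for all six wavelengths
    (2e5 photons per wavelength)."""
    return mc.depth_profile_by_wavelength(
        apple_table, n_photons=200_000, seed=mc.DEFAULT_SEED
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
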