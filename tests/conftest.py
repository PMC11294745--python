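import numpy as np
import pytest

from pmbrt import (
    BeamSpec,
    CollimatorSpec,
    PhantomGridSpec,
    Profile1D,
    default_calibration_triple,
    minibeam_dose,
)
from pmbrt.engine import _comb_factor, lateral_sigma


@pytest.fixture(scope="session")
def beam150():
    return BeamSpec(energy=150.0, mu_scale=8.0)


@pytest.fixture(scope="session")
def collimator():
    return CollimatorSpec()


@pytest.fixture(scope="session")
def minibeam_grid(beam150, collimator):
    """Standard minibeam plane: 150 MeV, c-t-c 2.8 mm, 6 cm air gap."""
    grid = PhantomGridSpec(x_extent=60.0, z_extent=170.0, air_gap=60.0)
    return minibeam_dose(beam150, collimator, grid)


@pytest.fixture(scope="session")
def shallow_grid(beam150, collimator):
    """Shallow plane (z <= 6 cm) for film-chain tests: cheaper to digitize."""
    grid = PhantomGridSpec(x_extent=60.0, z_extent=60.0, air_gap=60.0)
    return minibeam_dose(beam150, collimator, grid)


@pytest.fixture(scope="session")
def calibration_triple():
    return default_calibration_triple()


def make_comb_profile(
    beam,
    collimator,
    depth=10.0,
    air_gap=60.0,
    pitch=0.02,
    span=12.0,
    amplitude=8.0,
):
    """Analytic fine-pitch lateral comb profile at a given depth."""
    x = np.arange(-span, span + pitch / 2, pitch)
    sig = lateral_sigma(
        beam, depth, air_gap,
        exit_sigma=collimator.exit_sigma, exit_theta=collimator.exit_theta,
    )
    comb = _comb_factor(
        x, float(sig), collimator.slit_centers, collimator.slit_widths,
        np.ones(collimator.n_slits),
    )
    return Profile1D(x, amplitude * (comb + collimator.leakage), depth_tag=depth)


@pytest.fixture(scope="session")
def fine_comb(beam150, collimator):
    """0.02 mm-pitch comb profile at 1 cm depth (detector-kernel ready)."""
    return make_comb_profile(beam150, collimator)
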