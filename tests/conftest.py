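"""Shared fixtures: a small noise-free scene taken once through the chain.

Session-scoped fixtures are treated as read-only by every test.
"""

import numpy as np
import pytest

import sifpipe as sp
from sifpipe.grids import GridSpec

SEED = 11


@pytest.fixture(scope="session")
def atm():
    return sp.default_atmosphere()


@pytest.fixture(scope="session")
def grid32():
    return GridSpec(32, 32)


@pytest.fixture(scope="session")
def layout32(grid32):
    return sp.default_layout(grid32)


@pytest.fixture(scope="session")
def truths32(layout32, grid32):
    """Truth for all six overpasses on the 32x32 scene."""
    return sp.generate_truth(layout32, seed=SEED, grid=grid32)


@pytest.fixture(scope="session")
def truth32(truths32):
    """The 12:30 overpass (highest PAR of the morning block)."""
    return truths32[2]


@pytest.fixture(scope="session")
def refl32(truth32):
    return sp.truth_to_reflectance(truth32)


@pytest.fixture(scope="session")
def rad32(refl32, truth32, atm):
    """Noise-free at-sensor radiance at the true distance scale d = 1."""
    return sp.to_at_sensor(refl32, truth32, atm, snr=np.inf, d=1.0)


@pytest.fixture(scope="session")
def sfm32(rad32, refl32, atm):
    """Full three-step retrieval on the noise-free 32x32 scene."""
    return sp.SpectralFitModel(rad32, atm, reflectance=refl32).fit()


@pytest.fixture(scope="session")
def maps32(refl32, sfm32, truth32):
    from sifpipe import biophysics
    idx = biophysics.indices_from_reflectance(refl32)
    return sp.downscale_maps(refl32, sfm32.sif760, idx["fapar_chl"]), idx
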