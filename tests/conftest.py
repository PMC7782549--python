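"""Shared fixtures for the tmmspect test suite."""

import numpy as np
import pytest

from tmmspect.spectra import ppm_axis
from tmmspect.synthkit import (
    KineticParams,
    default_cell_schedule,
    default_invivo_schedule,
    simulate_kinetics,
    synth_dynamic_spectra,
)


@pytest.fixture
def cell_sched():
    return default_cell_schedule(100)


@pytest.fixture
def invivo_sched():
    return default_invivo_schedule()


@pytest.fixture
def tert_params():
    return KineticParams(m0=1.0, k_ap=0.008, k_pl=0.08)


@pytest.fixture
def alt_params():
    return KineticParams(m0=1.0, k_ap=0.008, k_pl=0.002)


@pytest.fixture
def small_axis():
    return ppm_axis(128, 20.0, 177.0)


@pytest.fixture
def tert_series(tert_params, cell_sched):
    """Noise-free TERT-like dynamic spectral series."""
    mag = simulate_kinetics(tert_params, cell_sched)
    return synth_dynamic_spectra(mag)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
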