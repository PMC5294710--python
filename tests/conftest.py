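"""Shared fixtures: small, fast slab/geometry configurations.

Photon budgets here are deliberately modest (thousands per depth point,
not the library default 1e5): every stochastic assertion in the suite is
quoted with its Monte Carlo error, so smaller batches change precision,
not correctness.
"""

import numpy as np
import pytest

from shgscatter import (
    DetectionGeometry,
    EmissionParams,
    OpticalProperties,
    SimulationConfig,
    TissueSlab,
)


@pytest.fixture
def geometry():
    return DetectionGeometry()


@pytest.fixture
def transparent_slab():
    """Index-matched slab with zero scattering at both wavelengths."""
    return TissueSlab(
        thickness=0.01,
        properties_by_wavelength={
            988.0: OpticalProperties(wavelength=988.0, n=1.33, mu_s=0.0, g=0.9),
            494.0: OpticalProperties(wavelength=494.0, n=1.33, mu_s=0.0, g=0.9),
        },
        n_surround_top=1.33,
        n_surround_bottom=1.33,
    )


@pytest.fixture
def scattering_slab():
    """Tissue-like slab: mu_s t ~ 2 at the SHG wavelength."""
    return TissueSlab(
        thickness=0.01,
        properties_by_wavelength={
            988.0: OpticalProperties(wavelength=988.0, n=1.40, mu_s=50.0, g=0.9),
            494.0: OpticalProperties(wavelength=494.0, n=1.40, mu_s=150.0, g=0.9),
        },
    )


@pytest.fixture
def depth_grid():
    return np.linspace(0.0, 0.01, 11)


@pytest.fixture
def small_config(depth_grid):
    return SimulationConfig(depth_grid=depth_grid, n_photons=4000, rng_seed=11)
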