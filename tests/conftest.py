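"""Shared fixtures: tiny spectral libraries, slab phantoms, and cached heavy runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from nirdosim import (
    OpticalProperties,
    ProbabilityMaps,
    SimConfig,
    SourceSpec,
    SpectralLibrary,
    VolumeGrid,
    build_phantom,
    run_mc,
)


@pytest.fixture(scope="session")
def two_tissue_library() -> SpectralLibrary:
    """Small library with two tissues at two wavelength nodes plus air."""
    return SpectralLibrary(
        {
            "A": {
                810: OpticalProperties(0.02, 10.0, 0.9, 1.37),
                850: OpticalProperties(0.04, 8.0, 0.8, 1.39),
            },
            "B": {
                810: OpticalProperties(0.08, 4.0, 0.7, 1.41),
                850: OpticalProperties(0.06, 6.0, 0.6, 1.43),
            },
            "air": {
                810: OpticalProperties(0.0, 0.0, 0.0, 1.0),
                850: OpticalProperties(0.0, 0.0, 0.0, 1.0),
            },
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)


def pure_absorber_phantom(mua: float = 0.1, shape=(40, 40, 30)):
    """Index-matched pure absorber slab filling the whole grid."""
    lib = SpectralLibrary({"abs": {810: OpticalProperties(mua, 0.0, 0.0, 1.0)}})
    grid = VolumeGrid(shape)
    pm = ProbabilityMaps(grid, {"abs": np.ones(shape)})
    return build_phantom(pm, lib, [810]), pm


def scattering_phantom(mua=0.02, mus=5.0, g=0.9, n=1.37, shape=(40, 40, 40)):
    """Homogeneous scattering cube filling the whole grid."""
    lib = SpectralLibrary({"m": {810: OpticalProperties(mua, mus, g, n)}})
    grid = VolumeGrid(shape)
    pm = ProbabilityMaps(grid, {"m": np.ones(shape)})
    return build_phantom(pm, lib, [810]), pm


@pytest.fixture(scope="session")
def small_scatter_run():
    """One cached scattering-cube run shared by bookkeeping tests."""
    phantom, _ = scattering_phantom()
    src = SourceSpec(
        kind="disk", center=(0.0, 0.0, -21.0), direction=(0.0, 0.0, 1.0),
        wavelength=810, radius=5.0,
    )
    cfg = SimConfig(n_photons=20_000, seed=7, roulette=False)
    return run_mc(phantom, [src], cfg), phantom, src, cfg
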