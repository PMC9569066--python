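"""Shared fixtures: phantoms and sector sets reused across test modules."""

import numpy as np
import pytest

from octaquant import macular_quadrants
from octaquant.phantom import (
    PhantomSpec,
    as_angiogram,
    generate_faz_phantom,
    generate_macular_phantom,
)


@pytest.fixture(scope="session")
def quadrants_962():
    return macular_quadrants(962)


@pytest.fixture(scope="session")
def clean_macular_phantom():
    """Noiseless macular phantom: vessel fraction 0.24, bright on dark."""
    spec = PhantomSpec(vessel_fraction=0.24, noise_sd=0.0, seed=11)
    image, truth = generate_macular_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noisy_macular_phantom():
    spec = PhantomSpec(vessel_fraction=0.30, noise_sd=12.0, seed=12)
    image, truth = generate_macular_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def disc_faz_phantom():
    """Dark disc of radius 50 px on bright textured background."""
    spec = PhantomSpec(faz_axes_px=(50.0, 50.0), noise_sd=10.0, seed=21)
    image, truth = generate_faz_phantom(spec)
    return spec, image, truth


@pytest.fixture
def angiogram_of():
    def _make(image, spec):
        return as_angiogram(np.asarray(image), spec)

    return _make
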