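"""Shared phantom fixtures.

The expensive phantom objects (high-resolution atlas, fractional PET atlas)
are built once per session; tests must not mutate them in place.
"""

from __future__ import annotations

import numpy as np
import pytest

from nudpa.io_preprocess import DynamicImage
from nudpa.phantoms import (
    PhantomSpec,
    make_atlas_phantom,
    make_pet_animal,
    pet_fractional_atlas,
)


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec(seed=11, noise_sigma=0.02)


@pytest.fixture(scope="session")
def mri_and_atlas(spec):
    return make_atlas_phantom(spec)


@pytest.fixture(scope="session")
def fractions(spec, mri_and_atlas):
    return pet_fractional_atlas(spec, mri_and_atlas[1])


@pytest.fixture(scope="session")
def clean_animal(spec, fractions):
    """Unperturbed, noisy metabolic acquisition plus its ground truth."""
    return make_pet_animal(spec, fractions)


@pytest.fixture()
def tiny_dynamic():
    """A small synthetic dynamic image for cheap preprocessing tests."""
    rng = np.random.default_rng(5)
    vox = rng.uniform(0.0, 1.0, (3, 20, 12, 12))
    schedule = [(i * 600.0, (i + 1) * 600.0) for i in range(3)]
    return DynamicImage(vox, (800.0, 800.0, 800.0), schedule)
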