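"""Shared fixtures: gradient schemes and small phantom studies.

Phantom grids here are scaled down (24x24x20) so the whole suite stays fast;
the generator's physics (forward model, stacked Rician noise, label scheme)
is identical to the full-size defaults.
"""

import numpy as np
import pytest

from dtiqa import dti_core
from dtiqa.io_formats import GradientScheme
from dtiqa.phantom import PhantomSpec, electrostatic_directions, generate

SMALL_GRID = (24, 24, 20)


@pytest.fixture(scope="session")
def directions32():
    return electrostatic_directions(32, seed=0)


@pytest.fixture(scope="session")
def scheme32(directions32):
    return GradientScheme(b_value=700.0, directions=directions32)


@pytest.fixture(scope="session")
def noisy_spec():
    return PhantomSpec(grid_shape=SMALL_GRID, noise_sigma=40.0, seed=1)


@pytest.fixture(scope="session")
def noisy_phantom(noisy_spec):
    return generate(noisy_spec)


@pytest.fixture(scope="session")
def clean_phantom():
    spec = PhantomSpec(grid_shape=SMALL_GRID, noise_sigma=0.0, seed=1)
    return generate(spec)


@pytest.fixture(scope="session")
def noisy_fit(noisy_phantom):
    study, _ = noisy_phantom
    return dti_core.fit_study(study)


def random_spd_tensors(n, rng, md_scale=1e-3):
    """Random positive-definite tensors with realistic diffusivity scale."""
    A = rng.standard_normal((n, 3, 3))
    spd = A @ A.transpose(0, 2, 1) + 0.1 * np.eye(3)
    spd *= md_scale / np.trace(spd, axis1=1, axis2=2)[:, None, None]
    return dti_core.matrix_to_tensor(spd)
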