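"""Shared fixtures: session-scoped phantom pairs so the expensive analytic
renderings happen once per run."""

from __future__ import annotations

import numpy as np
import pytest

from voxelreg.phantom import PhantomSpec, generate_phantom_pair, random_case_spec
from voxelreg.volume_io import Volume


@pytest.fixture(scope="session")
def coarse_spec():
    """Half-resolution phantom with a modest known motion, no noise."""
    return PhantomSpec.coarse(
        true_angles_zyx_deg=(4.0, 0.0, 0.0),
        true_translation_mm=(2.0, -3.0, 1.2),
    )


@pytest.fixture(scope="session")
def coarse_pair(coarse_spec):
    return generate_phantom_pair(coarse_spec)


@pytest.fixture(scope="session")
def static_coarse_pair():
    """Identity transform, zero jaw displacement, zero noise: fixed == moving."""
    spec = PhantomSpec.coarse(jaw_displacement=(0.0, 0.0, 0.0))
    return spec, generate_phantom_pair(spec)


@pytest.fixture(scope="session")
def default_spec():
    """Full-resolution (0.4 mm) phantom with a random within-bounds motion."""
    return random_case_spec(20260901, base=PhantomSpec())


@pytest.fixture(scope="session")
def default_pair(default_spec):
    return generate_phantom_pair(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_ramp_volume(shape=(12, 11, 10), spacing=(1.0, 1.0, 1.0), coeffs=(3.0, 5.0, 7.0), const=10.0):
    """Affine intensity field a·x + b·y + c·z + d on a grid (world mm)."""
    idx = np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij"), axis=-1
    )
    world = idx * np.asarray(spacing)
    data = world @ np.asarray(coeffs) + const
    return Volume(data, np.asarray(spacing))
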