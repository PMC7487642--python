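"""Shared fixtures: small phantoms and meshes generated at test time."""

import numpy as np
import pytest
import trimesh

from orbitmorph.synthetic import PhantomParams, generate_phantom_pair


def small_params(**overrides) -> PhantomParams:
    """Desk-sized phantom that segments in well under a second."""
    defaults = dict(
        cavity_mean_volume=1.2,
        voxel_spacing=0.5,
        shell_thickness=3.0,
        bump_sigma=3.0,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture(scope="session")
def small_pair():
    """One deformed small pair (T1, T2, truth), shared across tests."""
    params = small_params(bump_amplitudes=(0.8, 0.6), seed=3)
    return params, generate_phantom_pair(params)


@pytest.fixture(scope="session")
def quiet_pair():
    """Identity pair: no deformation, no rigid offset, no noise."""
    params = small_params(
        bump_amplitudes=(0.0, 0.0),
        rigid_rotation_deg=(0.0, 0.0, 0.0),
        rigid_translation=(0.0, 0.0, 0.0),
        noise_sd=0.0,
        seed=7,
    )
    return params, generate_phantom_pair(params)


@pytest.fixture()
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=17.9)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
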