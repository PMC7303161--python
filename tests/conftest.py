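"""Shared fixtures: small phantoms reused across test modules."""

import numpy as np
import pytest

from rvkinergy import ke_mapping as km
from rvkinergy import rv_geometry as rg
from rvkinergy import synthetic_data as sd


@pytest.fixture(scope="session")
def noiseless_spec():
    return sd.PhantomSpec(grid_shape=(32, 32, 12), noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    """Noiseless uniform-speed phantom: (spec, contours, field, truth)."""
    contours, truth = sd.make_geometry(noiseless_spec)
    field_, truth = sd.make_velocity_field(noiseless_spec, contours, truth)
    return noiseless_spec, contours, field_, truth


@pytest.fixture(scope="session")
def phantom_masks(noiseless_phantom):
    """Mesh-derived voxel masks of the noiseless phantom."""
    _, contours, field_, _ = noiseless_phantom
    mesh = rg.build_mesh(contours)
    return rg.mesh_to_mask(mesh, field_.grid_shape, field_.voxel_mm,
                           field_.origin_mm)


@pytest.fixture(scope="session")
def phantom_curve(noiseless_phantom, phantom_masks):
    _, _, field_, truth = noiseless_phantom
    return km.ke_curve(field_, phantom_masks, float(truth.volume_ml.max()))


def circle_stack(radius_mm=20.0, n_slices=10, thickness_mm=8.0,
                 n_vertices=96, center=(61.3, 60.9), z0=10.37, n_phases=2):
    """Analytic cylinder as a ContourStack (constant across phases)."""
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    poly = np.asarray(center) + radius_mm * np.stack(
        [np.cos(ang), np.sin(ang)], axis=1)
    zc = z0 + (np.arange(n_slices) + 0.5) * thickness_mm
    return rg.ContourStack(
        [[poly.copy() for _ in range(n_slices)] for _ in range(n_phases)],
        zc, thickness_mm, n_phases)
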