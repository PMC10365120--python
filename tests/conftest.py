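"""Shared fixtures: gradient scheme, small phantoms, a reduced SLF scene.

Everything is generated programmatically at collection time; session scope
keeps the expensive pieces (direction optimization, scene rasterization)
to one computation per run.
"""
import numpy as np
import pytest

import tractometry as tm


@pytest.fixture(scope="session")
def gtab():
    """The default emulated acquisition: 3 b=0 + 64 directions at b=1000."""
    return tm.make_gradient_table()


@pytest.fixture(scope="session")
def small_scene():
    """Reduced-grid SLF-like scene (1.5 mm voxels) used across modules."""
    return tm.make_slf_like_scene(shape=(30, 36, 20))


@pytest.fixture(scope="session")
def scene_field(small_scene):
    """Ground-truth tensor field + per-bundle masks of the reduced scene."""
    return tm.rasterize_tensor_field(
        small_scene.bundles, small_scene.shape, small_scene.affine)


@pytest.fixture(scope="session")
def noiseless_subject(small_scene, scene_field, gtab):
    """Noise-free DWI of the reduced scene plus its fitted scalar maps."""
    field, _ = scene_field
    dwi = tm.simulate_dwi(field, gtab, snr=None)
    fit = tm.DiffusionTensorModel(dwi).fit()
    return dwi, fit, fit.scalar_maps()


def straight_slab(length_mm=30.0, half_width_vox=3, voxel=1.5,
                  eigvals=(1.7e-3, 0.3e-3, 0.3e-3)):
    """A uniform x-aligned bundle slab, built voxel-by-voxel (no caps).

    The slab occupies voxels whose centers span exactly ``length_mm`` along
    x, with principal direction +x; the background is isotropic (FA 0).
    Returns (field, affine, (x_start_mm, x_end_mm), center_yz_mm).
    """
    n_slab = int(round(length_mm / voxel)) + 1  # centers span length_mm
    shape = (n_slab + 8, 2 * half_width_vox + 3, 2 * half_width_vox + 3)
    affine = np.diag([voxel, voxel, voxel, 1.0])
    cy, cz = shape[1] // 2, shape[2] // 2

    ev_bg = np.array([0.7e-3, 0.7e-3, 0.7e-3])
    ev_wm = np.sort(np.asarray(eigvals, dtype=float))[::-1]
    eigvals_grid = np.broadcast_to(ev_bg, shape + (3,)).copy()
    eigvecs_grid = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    slab = np.zeros(shape, dtype=bool)
    slab[4:4 + n_slab,
         cy - half_width_vox:cy + half_width_vox + 1,
         cz - half_width_vox:cz + half_width_vox + 1] = True
    eigvals_grid[slab] = ev_wm  # e1 is the identity's x column already

    tensors = np.einsum("...ij,...j,...kj->...ik", eigvecs_grid,
                        eigvals_grid, eigvecs_grid)
    coeffs = np.stack([tensors[..., 0, 0], tensors[..., 1, 1],
                       tensors[..., 2, 2], tensors[..., 0, 1],
                       tensors[..., 0, 2], tensors[..., 1, 2]], axis=-1)
    field = tm.DiffusionTensorFit(
        coeffs=coeffs, eigvals=eigvals_grid, eigvecs=eigvecs_grid,
        s0=np.full(shape, 1000.0), affine=affine,
        mask=np.ones(shape, dtype=bool))
    x_range = (4 * voxel, (4 + n_slab - 1) * voxel)
    return field, affine, x_range, (cy * voxel, cz * voxel)
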