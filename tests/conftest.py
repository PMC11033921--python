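import numpy as np
import pytest

from tractval import LabeledVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def random_affine(rng, shear=True):
    """A random invertible voxel-to-world affine: anisotropic scaling, small
    shear, and a translation."""
    scales = rng.uniform(0.7, 2.0, size=3)
    A = np.diag(scales)
    if shear:
        A = A + rng.uniform(-0.3, 0.3, size=(3, 3)) * (1 - np.eye(3))
    if abs(np.linalg.det(A)) < 1e-3:  # exceedingly rare; nudge back to safety
        A = A + 0.5 * np.eye(3)
    aff = np.eye(4)
    aff[:3, :3] = A
    aff[:3, 3] = rng.uniform(-10, 10, size=3)
    return aff


def random_mask_volume(rng, shape=(10, 10, 10), n_voxels=30, affine=None, label=""):
    mask = np.zeros(shape, dtype=np.uint8)
    flat = rng.choice(np.prod(shape), size=min(n_voxels, np.prod(shape)), replace=False)
    mask.ravel()[flat] = 1
    if affine is None:
        affine = random_affine(rng)
    return LabeledVolume(mask, affine, label)


def all_voxel_world_centers(vol):
    """Oracle helper: explicit world centers of *every* voxel, built from a
    meshgrid rather than the library's index paths."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in vol.shape), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    A, t = vol.affine[:3, :3], vol.affine[:3, 3]
    return idx, idx @ A.T + t
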