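import numpy as np
import pytest

from trabstiff.volumes import VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def digital_ball(radius: int, pad: int = 2, spacing: float = 1.0) -> VoxelVolume:
    """Binary ball: voxel centers within `radius` of the cube center."""
    n = 2 * (radius + pad) + 1
    c = (n - 1) / 2
    ax = np.arange(n) - c
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return VoxelVolume((d2 <= radius**2).astype(np.uint8), spacing, "binary")


def axis_slab(thickness: int, n: int = 16, axis: int = 2, spacing: float = 1.0) -> VoxelVolume:
    """Binary slab of `thickness` voxels spanning the volume, centered."""
    data = np.zeros((n, n, n), dtype=np.uint8)
    start = (n - thickness) // 2
    sl = [slice(None)] * 3
    sl[axis] = slice(start, start + thickness)
    data[tuple(sl)] = 1
    return VoxelVolume(data, spacing, "binary")


def digital_cylinder(radius: int, n: int = None, axis: int = 2, spacing: float = 1.0) -> VoxelVolume:
    """Binary cylinder along `axis` spanning the full volume."""
    if n is None:
        n = 2 * radius + 7
    c = (n - 1) / 2
    ax = np.arange(n) - c
    planes = [0, 1, 2]
    planes.remove(axis)
    d2 = np.zeros((n, n, n))
    shapes = [(n, 1, 1), (1, n, 1), (1, 1, n)]
    d2 = ax.reshape(shapes[planes[0]]) ** 2 + ax.reshape(shapes[planes[1]]) ** 2
    d2 = np.broadcast_to(d2, (n, n, n))
    return VoxelVolume((d2 <= radius**2).astype(np.uint8), spacing, "binary")


def random_blob_volume(rng, shape=(14, 14, 14), fill=0.3) -> VoxelVolume:
    """Random smoothed-noise binary volume with a guaranteed foreground."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5)
    level = np.quantile(field, 1 - fill)
    data = (field >= level).astype(np.uint8)
    if data.sum() == 0:
        data[tuple(s // 2 for s in shape)] = 1
    return VoxelVolume(data, 1.0, "binary")


def brute_force_thickness(mask: np.ndarray) -> np.ndarray:
    """O(n^2) inscribed-sphere oracle for the local thickness map (voxels).

    For every candidate center t the largest inscribed radius is the exact
    distance to the nearest background voxel center (computed by scanning
    all background voxels); a point p is covered by that sphere when
    ||p - t|| < r(t), and keeps the largest diameter over all centers.
    """
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    if len(bg) == 0:
        raise ValueError("oracle needs background voxels")
    # exact integer squared distances: no float rounding at sphere surfaces
    d2_bg = ((fg[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    d2_pt = ((fg[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2)
    covered = d2_pt < d2_bg[None, :]  # p covered by sphere centered at t
    diam = np.where(covered, 2 * np.sqrt(d2_bg)[None, :], 0.0).max(axis=1)
    out[tuple(fg.T)] = diam
    return out
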