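"""Local trabecular thickness and spacing by maximal inscribed spheres.

The local thickness at a point p of the segmented bone T is the diameter of
the largest sphere that contains p while lying completely inside T:

    Tb.Th(p) = 2 * max{ r : p in B_r(t), B_r(t) subset of T }.

Tb.Sp is the same quantity evaluated on the complement (marrow). Maps are in
mm, zero outside their respective domain, and computed with the classical
distance-transform / sphere-painting scheme: the Euclidean distance transform
gives the largest inscribed radius at each candidate center, and spheres are
painted in decreasing radius order so each voxel keeps the diameter of the
largest sphere covering it. Sphere membership uses voxel centers with exact
Euclidean distances, so no grid-direction bias is introduced. No correction
is applied at volume borders (spheres are limited by the image boundary
implicitly through the distance transform's treatment of the border as bone
or marrow continuation: the EDT only sees real background voxels, so
structures touching the border are measured as if they continued outward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from trabstiff.volumes import VoxelVolume

__all__ = ["ThicknessMap", "local_thickness", "local_spacing", "bvtv"]


@dataclass
class ThicknessMap:
    """A Tb.Th or Tb.Sp map (mm) on the voxel grid of its source volume."""

    values: VoxelVolume
    source: str  # 'Tb.Th' or 'Tb.Sp'

    def __post_init__(self):
        if self.source not in ("Tb.Th", "Tb.Sp"):
            raise ValueError("source must be 'Tb.Th' or 'Tb.Sp'")
        if self.values.kind != "map":
            raise ValueError("ThicknessMap values must be a 'map' volume")
        if np.any(self.values.data < 0):
            raise ValueError("thickness values must be non-negative")


@njit(cache=True)
def _paint_spheres(order_x, order_y, order_z, r2s, out):
    """Paint diameters 2*sqrt(r2) over all voxels with ||q-t||^2 < r2.

    Squared radii are exact integers (squared lattice distances), so the
    strict inequality never leaks across the sphere boundary through float
    rounding. Centers come sorted by decreasing radius so larger spheres
    win early; `out` keeps the running maximum regardless.
    """
    nx, ny, nz = out.shape
    for n in range(order_x.shape[0]):
        cx, cy, cz = order_x[n], order_y[n], order_z[n]
        r2 = r2s[n]
        d = 2.0 * np.sqrt(r2)
        ir = int(np.ceil(np.sqrt(r2)))
        x0, x1 = max(cx - ir, 0), min(cx + ir, nx - 1)
        y0, y1 = max(cy - ir, 0), min(cy + ir, ny - 1)
        z0, z1 = max(cz - ir, 0), min(cz + ir, nz - 1)
        for x in range(x0, x1 + 1):
            dx2 = (x - cx) * (x - cx)
            if dx2 >= r2:
                continue
            for y in range(y0, y1 + 1):
                dxy2 = dx2 + (y - cy) * (y - cy)
                if dxy2 >= r2:
                    continue
                for z in range(z0, z1 + 1):
                    if dxy2 + (z - cz) * (z - cz) < r2:
                        if out[x, y, z] < d:
                            out[x, y, z] = d
    return out


def _thickness_voxels(mask: np.ndarray) -> np.ndarray:
    """Local thickness of a boolean mask, in voxel units."""
    # EDT: distance from each foreground voxel to the nearest background
    # voxel center; any radius r < EDT yields an inscribed sphere. Squared
    # distances are integers on the unit lattice.
    edt2 = np.rint(ndimage.distance_transform_edt(mask) ** 2).astype(np.int64)
    fx, fy, fz = np.nonzero(mask)
    r2 = edt2[fx, fy, fz]
    order = np.argsort(-r2, kind="stable")
    out = np.zeros(mask.shape, dtype=np.float64)
    _paint_spheres(
        fx[order].astype(np.int64),
        fy[order].astype(np.int64),
        fz[order].astype(np.int64),
        r2[order],
        out,
    )
    return out


def local_thickness(binary: VoxelVolume) -> ThicknessMap:
    """Tb.Th map in mm; zero on background."""
    if binary.kind != "binary":
        raise ValueError("local_thickness expects a binary volume")
    mask = binary.data.astype(bool)
    if not mask.any():
        raise ValueError("empty foreground")
    th = _thickness_voxels(mask) * binary.spacing_mm
    vol = VoxelVolume(th, spacing_mm=binary.spacing_mm, kind="map")
    return ThicknessMap(values=vol, source="Tb.Th")


def local_spacing(binary: VoxelVolume) -> ThicknessMap:
    """Tb.Sp map in mm (thickness of the marrow phase); zero on foreground."""
    if binary.kind != "binary":
        raise ValueError("local_spacing expects a binary volume")
    mask = binary.data.astype(bool)
    if mask.all():
        raise ValueError("full foreground: no background phase")
    sp = _thickness_voxels(~mask) * binary.spacing_mm
    vol = VoxelVolume(sp, spacing_mm=binary.spacing_mm, kind="map")
    return ThicknessMap(values=vol, source="Tb.Sp")


def bvtv(binary: VoxelVolume) -> float:
    """Bone volume fraction: foreground voxels over total voxels."""
    if binary.kind != "binary":
        raise ValueError("bvtv expects a binary volume")
    return float(np.count_nonzero(binary.data)) / binary.data.size
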