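"""Apparent stiffness tensors in Voigt notation.

The apparent stiffness of a trabecular bone cube relates volume-averaged
stress and strain through Hooke's law, sigma_ij = C_ijkl eps_kl. The
fourth-order tensor is carried here as a 6x6 matrix in Voigt order
(11, 22, 33, 23, 13, 12) with the engineering shear-strain convention
(gamma = 2 eps for the shear rows/columns), the common biomechanics choice.
All entries are in MPa.

Note on norms: the Frobenius norm of the plain Voigt 6x6 matrix is *not*
invariant under rotations of the underlying fourth-order tensor (the Mandel
scaling would be). Error metrics in this package deliberately use the plain
6x6 matrices, treating the stiffness as a vector of 36 entries.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VOIGT_PAIRS",
    "StiffnessMatrix",
    "voigt_to_tensor",
    "tensor_to_voigt",
    "rotate_stiffness",
    "reynolds_glyph",
    "is_spd",
    "isotropic_stiffness",
    "mandel_norm",
]

#: index pairs (i, j) for the Voigt rows/columns 0..5
VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))

_VOIGT_OF = {}
for _I, (_i, _j) in enumerate(VOIGT_PAIRS):
    _VOIGT_OF[(_i, _j)] = _I
    _VOIGT_OF[(_j, _i)] = _I


@dataclass
class StiffnessMatrix:
    """6x6 apparent stiffness in MPa, Voigt order (11,22,33,23,13,12)."""

    entries: np.ndarray
    symmetric: bool = False
    units: str = field(default="MPa", repr=False)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (6, 6):
            raise ValueError(f"stiffness must be 6x6, got {self.entries.shape}")
        if self.symmetric:
            nrm = np.linalg.norm(self.entries)
            asym = np.abs(self.entries - self.entries.T).max()
            if nrm > 0 and asym > 1e-6 * nrm:
                raise ValueError(
                    f"symmetric flag set but relative asymmetry {asym / nrm:.2e} > 1e-6"
                )

    @property
    def matrix(self) -> np.ndarray:
        return self.entries

    def frobenius_norm(self) -> float:
        return float(np.linalg.norm(self.entries))

    def symmetrized(self) -> "StiffnessMatrix":
        return StiffnessMatrix(0.5 * (self.entries + self.entries.T), symmetric=True)

    # ---- serialization ----------------------------------------------------
    def to_csv(self, path) -> None:
        header = (
            "# apparent stiffness, Voigt order 11,22,33,23,13,12, "
            "engineering shear convention, units MPa\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.entries, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "StiffnessMatrix":
        with open(path) as fh:
            txt = [ln for ln in fh if not ln.startswith("#")]
        arr = np.loadtxt(io.StringIO("".join(txt)), delimiter=",")
        return cls(arr)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "voigt_order": "11,22,33,23,13,12",
                    "shear_convention": "engineering",
                    "units": self.units,
                    "entries": self.entries.tolist(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "StiffnessMatrix":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["entries"]))


def _as_matrix(C) -> np.ndarray:
    if isinstance(C, StiffnessMatrix):
        return C.entries
    C = np.asarray(C, dtype=float)
    if C.shape != (6, 6):
        raise ValueError("expected a 6x6 stiffness matrix")
    return C


def voigt_to_tensor(C) -> np.ndarray:
    """Expand a Voigt 6x6 stiffness into the full 3x3x3x3 tensor.

    With the engineering shear convention the stiffness entries map without
    scale factors: C_ijkl = C_voigt[I(ij), J(kl)]. Minor symmetries hold by
    construction.
    """
    M = _as_matrix(C)
    T = np.empty((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    T[i, j, k, l] = M[_VOIGT_OF[(i, j)], _VOIGT_OF[(k, l)]]
    return T


def tensor_to_voigt(T) -> StiffnessMatrix:
    """Contract a minor-symmetric fourth-order tensor to Voigt 6x6 form."""
    T = np.asarray(T, dtype=float)
    if T.shape != (3, 3, 3, 3):
        raise ValueError("expected a 3x3x3x3 tensor")
    M = np.empty((6, 6))
    for I, (i, j) in enumerate(VOIGT_PAIRS):
        for J, (k, l) in enumerate(VOIGT_PAIRS):
            M[I, J] = T[i, j, k, l]
    return StiffnessMatrix(M)


def _check_rotation(R) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("matrix is not orthogonal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection (det = -1), not a rotation")
    return R


def rotate_stiffness(C, R) -> StiffnessMatrix:
    """Rotate a stiffness: C'_ijkl = R_ip R_jq R_kr R_ls C_pqrs."""
    R = _check_rotation(R)
    T = voigt_to_tensor(C)
    Tp = np.einsum("ip,jq,kr,ls,pqrs->ijkl", R, R, R, R, T, optimize=True)
    return tensor_to_voigt(Tp)


def reynolds_glyph(C, directions) -> np.ndarray:
    """Directional modulus r(n) = C_ijkl n_i n_j n_k n_l for unit vectors n.

    The resulting radii (MPa) plotted over the sphere are the Reynolds glyph
    of the stiffness; it is even in n and isotropic tensors give a constant.
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    nrm = np.linalg.norm(dirs, axis=1)
    if np.any(nrm < 1e-12):
        raise ValueError("zero direction vector")
    dirs = dirs / nrm[:, None]
    T = voigt_to_tensor(C)
    return np.einsum("ijkl,ni,nj,nk,nl->n", T, dirs, dirs, dirs, dirs, optimize=True)


def export_glyph_csv(C, directions, path) -> None:
    """Write (direction, radius) rows of the Reynolds glyph for plotting."""
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    radii = reynolds_glyph(C, dirs)
    with open(path, "w") as fh:
        fh.write("# Reynolds glyph radii, MPa\nnx,ny,nz,radius\n")
        for d, r in zip(dirs / np.linalg.norm(dirs, axis=1)[:, None], radii):
            fh.write(f"{d[0]:.8f},{d[1]:.8f},{d[2]:.8f},{r:.6f}\n")


def is_spd(C) -> bool:
    """True iff the (symmetric) 6x6 stiffness is positive definite."""
    M = _as_matrix(C)
    if not np.allclose(M, M.T, atol=1e-6 * max(1.0, np.linalg.norm(M))):
        raise ValueError("is_spd requires a symmetric matrix")
    return bool(np.linalg.eigvalsh(0.5 * (M + M.T)).min() > 0)


def isotropic_stiffness(young_modulus: float, poisson_ratio: float) -> StiffnessMatrix:
    """Isotropic Voigt stiffness from E (MPa) and nu."""
    E, nu = float(young_modulus), float(poisson_ratio)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    M = np.zeros((6, 6))
    M[:3, :3] = lam
    M[np.arange(3), np.arange(3)] = lam + 2 * mu
    M[np.arange(3, 6), np.arange(3, 6)] = mu
    return StiffnessMatrix(M, symmetric=True)


def mandel_norm(C) -> float:
    """Rotation-invariant Frobenius norm (Mandel scaling of the 6x6)."""
    M = _as_matrix(C).copy()
    s = np.sqrt(2.0)
    scale = np.array([1, 1, 1, s, s, s])
    return float(np.linalg.norm(M * np.outer(scale, scale)))
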