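"""Fabric tensors from the EGI and a power-law stiffness baseline.

The global structure tensor (GST) is the second (or fourth) directional
moment of the EGI mass distribution. MIL-style tensors arise by filtering
the EGI density with a zonal kernel -- |cos(theta)| reproduces the classic
mean-intercept-length construction, a concentrated von Mises-Fisher bump
gives a GMIL-style variant -- taking the reciprocal of the filtered
distribution, and fitting a second-order tensor over directions by least
squares.

The stiffness baseline is an orthotropic Zysset-Curnier-type power law
driven by bone volume fraction rho and the (trace-3 normalized) fabric
eigenvalues m_i:

    C_iiii = c_a * rho^k * m_i^(2q)
    C_iijj = c_b * rho^k * (m_i m_j)^q     (i != j)
    C_ijij = c_c * rho^k * (m_i m_j)^q     (shear, engineering convention)

in the fabric eigenframe, rotated back to the lab frame. The five constants
(c_a, c_b, c_c, k, q) are fitted in log space on training data only, per
cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from trabstiff.egi import SphericalMap, grid_directions
from trabstiff.sphharm import ZonalKernel, sht_forward, sht_inverse, zonal_convolve
from trabstiff.stiffness import StiffnessMatrix, rotate_stiffness

__all__ = [
    "FabricTensor",
    "gst_from_egi",
    "mil_from_egi",
    "FabricModelParams",
    "fit_fabric_model",
    "predict_fabric",
    "abs_cos_kernel",
    "vmf_kernel",
]


@dataclass
class FabricTensor:
    """Symmetric fabric tensor of order 2 (3x3) or 4 (3x3x3x3)."""

    order: int
    components: np.ndarray
    normalization: str = "trace3"

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.order == 2:
            if self.components.shape != (3, 3):
                raise ValueError("order-2 fabric must be 3x3")
            if not np.allclose(self.components, self.components.T, atol=1e-9):
                raise ValueError("fabric tensor must be symmetric")
        elif self.order == 4:
            if self.components.shape != (3, 3, 3, 3):
                raise ValueError("order-4 fabric must be 3x3x3x3")
        else:
            raise ValueError("order must be 2 or 4")

    def eigensystem(self):
        """Eigenvalues (descending) and matching eigenvector columns (order 2)."""
        if self.order != 2:
            raise ValueError("eigensystem is defined for order-2 fabric")
        w, V = np.linalg.eigh(self.components)
        idx = np.argsort(w)[::-1]
        w, V = w[idx], V[:, idx]
        # deterministic signs: largest-magnitude entry of each vector positive
        for c in range(3):
            j = np.argmax(np.abs(V[:, c]))
            if V[j, c] < 0:
                V[:, c] = -V[:, c]
        if np.linalg.det(V) < 0:
            V[:, 2] = -V[:, 2]
        return w, V

    def degree_of_anisotropy(self) -> float:
        w, _ = self.eigensystem()
        return float(w[0] / w[-1])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "order": self.order,
                    "normalization": self.normalization,
                    "components": self.components.tolist(),
                },
                fh,
                indent=1,
            )


def _single_channel_mass(egi: SphericalMap, channel: int = 0) -> np.ndarray:
    vals = egi.values[channel]
    if np.any(vals < 0):
        raise ValueError("EGI values must be non-negative")
    if vals.sum() <= 0:
        raise ValueError("EGI has zero total mass")
    return vals


def gst_from_egi(egi: SphericalMap, order: int = 2, channel: int = 0) -> FabricTensor:
    """Global structure tensor: directional moment of the EGI mass."""
    mass = _single_channel_mass(egi, channel)
    v = grid_directions(egi.grid)
    if order == 2:
        M = np.einsum("ab,abi,abj->ij", mass, v, v, optimize=True)
        M /= np.trace(M) / 3.0
        return FabricTensor(order=2, components=0.5 * (M + M.T))
    if order == 4:
        M = np.einsum("ab,abi,abj,abk,abl->ijkl", mass, v, v, v, v, optimize=True)
        tr = np.einsum("iijj->", M)  # full trace; normalize analogously
        M *= 3.0 / tr
        return FabricTensor(order=4, components=M)
    raise ValueError("order must be 2 or 4")


def abs_cos_kernel(n_coeff: int) -> ZonalKernel:
    """Zonal coefficients of h(theta) = |cos theta| (even degrees only)."""
    # hhat_l = 2*pi*N_l0 * int_-1^1 |x| P_l(x) dx, computed by quadrature
    from numpy.polynomial.legendre import leggauss

    x, w = leggauss(64)
    coeffs = np.zeros(n_coeff)
    from scipy.special import eval_legendre

    for l in range(0, n_coeff, 2):
        nl = np.sqrt((2 * l + 1) / (4 * np.pi))
        coeffs[l] = 2 * np.pi * nl * np.sum(w * np.abs(x) * eval_legendre(l, x))
    return ZonalKernel(coeffs)


def vmf_kernel(n_coeff: int, kappa: float = 10.0) -> ZonalKernel:
    """Zonal coefficients of the symmetrized von Mises-Fisher bump.

    Uses (exp(kappa*|x|) - 1), antipodally symmetric, as a concentrated
    stand-in for generalized-MIL filtering.
    """
    from numpy.polynomial.legendre import leggauss
    from scipy.special import eval_legendre

    x, w = leggauss(128)
    h = np.exp(kappa * np.abs(x)) - 1.0
    h /= np.trapezoid(np.exp(kappa * np.abs(np.linspace(-1, 1, 512))) - 1, dx=2 / 511)
    coeffs = np.zeros(n_coeff)
    for l in range(0, n_coeff, 2):
        nl = np.sqrt((2 * l + 1) / (4 * np.pi))
        coeffs[l] = 2 * np.pi * nl * np.sum(w * h * eval_legendre(l, x))
    return ZonalKernel(coeffs)


def mil_from_egi(
    egi: SphericalMap,
    kernel: str = "abs_cos",
    kappa: float = 10.0,
    order: int = 2,
    channel: int = 0,
) -> FabricTensor:
    """MIL-style fabric: filter the EGI density, invert, fit a tensor.

    kernel='abs_cos' gives the classic mean-intercept-length analogue;
    kernel='vmf' a concentrated (GMIL-style) variant with concentration
    kappa (a synthetic stand-in for generalized-MIL kernels).
    """
    mass = _single_channel_mass(egi, channel)
    grid = egi.grid
    density = mass / grid.area_weights  # mass-per-bin -> density on S2
    smap = SphericalMap(grid=grid, channels=("density",), values=density[None])
    coeffs = sht_forward(smap)
    if kernel == "abs_cos":
        zk = abs_cos_kernel(grid.b)
    elif kernel == "vmf":
        zk = vmf_kernel(grid.b, kappa)
    else:
        raise ValueError("kernel must be abs_cos|vmf")
    filtered = sht_inverse(zonal_convolve(coeffs, zk), grid).values[0]
    floor = 1e-12 * max(abs(filtered).max(), 1e-300)
    if np.all(filtered <= floor):
        raise ValueError("filtered distribution is zero everywhere")
    recip = 1.0 / np.clip(filtered, floor, None)

    v = grid_directions(grid).reshape(-1, 3)
    w = grid.area_weights.ravel()
    y = recip.ravel()
    if order == 2:
        # least-squares fit of y(n) ~ n^T F n over directions, area-weighted
        design = np.stack(
            [
                v[:, 0] ** 2, v[:, 1] ** 2, v[:, 2] ** 2,
                2 * v[:, 1] * v[:, 2], 2 * v[:, 0] * v[:, 2], 2 * v[:, 0] * v[:, 1],
            ],
            axis=1,
        )
        sw = np.sqrt(w)
        sol, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        F = np.array(
            [
                [sol[0], sol[5], sol[4]],
                [sol[5], sol[1], sol[3]],
                [sol[4], sol[3], sol[2]],
            ]
        )
        F *= 3.0 / np.trace(F)
        return FabricTensor(order=2, components=F)
    if order == 4:
        M = np.einsum("a,a,ai,aj,ak,al->ijkl", w, y, v, v, v, v, optimize=True)
        M *= 3.0 / np.einsum("iijj->", M)
        return FabricTensor(order=4, components=M)
    raise ValueError("order must be 2 or 4")


# ---------------------------------------------------------------------------
# Power-law stiffness baseline
# ---------------------------------------------------------------------------


@dataclass
class FabricModelParams:
    """Fitted constants of the orthotropic power-law baseline."""

    family: str  # which fabric feeds the model, e.g. 'gst' or 'mil'
    c_a: float  # axial constant (MPa)
    c_b: float  # cross constant (MPa)
    c_c: float  # shear constant (MPa)
    k_rho: float  # density exponent
    q_fabric: float  # fabric exponent
    r2_log: float = float("nan")  # fit diagnostic in log space
    n_train: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FabricModelParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def _orthotropic_samples(record):
    """(rho, m, C_in_fabric_frame) for one (bvtv, fabric, stiffness) record."""
    rho, fabric, C = record
    m, V = fabric.eigensystem()
    Cr = rotate_stiffness(C, V.T)  # lab -> fabric frame
    return rho, m, Cr.entries


def fit_fabric_model(records, family: str = "gst", min_records: int = 20) -> FabricModelParams:
    """Least-squares log-space fit of the power-law constants.

    records: iterable of (bvtv, FabricTensor(order 2), StiffnessMatrix),
    training folds only. The nine orthotropic components of each observed
    stiffness (rotated into its fabric frame) provide the regression rows.
    """
    records = list(records)
    if len(records) < min_records:
        raise ValueError(f"need at least {min_records} training records")
    rows, targets = [], []
    for rec in records:
        rho, m, C = _orthotropic_samples(rec)
        if not (0 < rho < 1) or np.any(m <= 0):
            raise ValueError("records need bvtv in (0,1) and positive fabric eigenvalues")
        lr = np.log(rho)
        for i in range(3):
            cii = C[i, i]
            if cii > 0:
                rows.append([1, 0, 0, lr, 2 * np.log(m[i])])
                targets.append(np.log(cii))
        for (i, j) in ((0, 1), (0, 2), (1, 2)):
            cij = C[i, j]
            if cij > 0:
                rows.append([0, 1, 0, lr, np.log(m[i] * m[j])])
                targets.append(np.log(cij))
        for shear, (i, j) in zip((3, 4, 5), ((1, 2), (0, 2), (0, 1))):
            cs = C[shear, shear]
            if cs > 0:
                rows.append([0, 0, 1, lr, np.log(m[i] * m[j])])
                targets.append(np.log(cs))
    A = np.asarray(rows)
    y = np.asarray(targets)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design (degenerate training set)")
    sol, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_res = np.sum((A @ sol - y) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FabricModelParams(
        family=family,
        c_a=float(np.exp(sol[0])),
        c_b=float(np.exp(sol[1])),
        c_c=float(np.exp(sol[2])),
        k_rho=float(sol[3]),
        q_fabric=float(sol[4]),
        r2_log=float(r2),
        n_train=len(records),
    )


def predict_fabric(params: FabricModelParams, bvtv: float, fabric: FabricTensor) -> StiffnessMatrix:
    """Closed-form baseline stiffness for one specimen."""
    if not (0 < bvtv < 1):
        raise ValueError("bvtv must lie in (0, 1)")
    m, V = fabric.eigensystem()
    rk = bvtv**params.k_rho
    q = params.q_fabric
    C = np.zeros((6, 6))
    for i in range(3):
        C[i, i] = params.c_a * rk * m[i] ** (2 * q)
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        C[i, j] = C[j, i] = params.c_b * rk * (m[i] * m[j]) ** q
    for shear, (i, j) in zip((3, 4, 5), ((1, 2), (0, 2), (0, 1))):
        C[shear, shear] = params.c_c * rk * (m[i] * m[j]) ** q
    return rotate_stiffness(StiffnessMatrix(C, symmetric=True), V)  # fabric -> lab
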