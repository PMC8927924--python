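"""Spherical-harmonic analysis, zonal convolution, rotation, and pooling.

Conventions: orthonormal complex spherical harmonics Y_l^m with the
Condon-Shortley phase (as in scipy.special.sph_harm_y). The forward
transform is the quadrature discretization of

    fhat_l^m = integral_{S2} f(x) conj(Y_l^m(x)) dx,

exact for maps band-limited below the grid bandwidth b (the Fejer-type
elevation weights integrate the polynomial integrands exactly). Convolution
of f with a zonal kernel h is diagonal in degree:

    yhat_l^m = 2*pi*sqrt(4*pi/(2l+1)) * fhat_l^m * hhat_l^0.

Rotations act on coefficients through Wigner-D blocks: for g(x) = f(R^-1 x)
with ZYZ Euler angles (a, b, c) of R,

    ghat_l^{m'} = sum_m e^{-i m' a} d^l_{m'm}(b) e^{-i m c} fhat_l^m.

A private real-harmonics fast path (`real_transforms`) backs the neural
network, where all tensors stay real.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import lgamma

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from trabstiff.egi import SphericalGrid, SphericalMap, make_grid

__all__ = [
    "SHCoeffs",
    "ZonalKernel",
    "sht_forward",
    "sht_inverse",
    "zonal_convolve",
    "rotate_coeffs",
    "pool_half",
    "global_pool",
    "coeff_index",
    "degrees_of_coeffs",
    "zonal_scale",
    "identity_kernel",
    "wigner_d_matrix",
    "real_transforms",
]


def coeff_index(l: int, m: int) -> int:
    """Flat index of (l, m) in the packed coefficient layout, l^2 + l + m."""
    return l * l + l + m


@lru_cache(maxsize=64)
def degrees_of_coeffs(b: int) -> np.ndarray:
    """Degree l of each packed coefficient index for bandwidth b."""
    return np.concatenate([np.full(2 * l + 1, l) for l in range(b)])


@lru_cache(maxsize=64)
def _orders_of_coeffs(b: int) -> np.ndarray:
    return np.concatenate([np.arange(-l, l + 1) for l in range(b)])


@dataclass
class SHCoeffs:
    """Packed complex coefficients fhat_l^m, 0 <= l < b, |m| <= l, per channel.

    values has shape (n_channels, b*b); index of (l, m) is l^2 + l + m.
    """

    b: int
    channels: tuple
    values: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=complex))
        if self.values.shape[1] != self.b * self.b:
            raise ValueError(
                f"expected {self.b * self.b} coefficients per channel, "
                f"got {self.values.shape[1]}"
            )
        self.channels = tuple(self.channels)
        if len(self.channels) != self.values.shape[0]:
            raise ValueError("channel labels must match the number of channels")

    def get(self, channel: int, l: int, m: int) -> complex:
        if not (0 <= l < self.b and -l <= m <= l):
            raise IndexError(f"(l={l}, m={m}) outside bandwidth {self.b}")
        return complex(self.values[channel, coeff_index(l, m)])

    def degree_energy(self, channel: int = 0) -> np.ndarray:
        """Per-degree energy sum_m |fhat_l^m|^2."""
        ls = degrees_of_coeffs(self.b)
        e = np.abs(self.values[channel]) ** 2
        return np.bincount(ls, weights=e, minlength=self.b)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("coeffs", data=self.values)
            ds.attrs["bandwidth"] = self.b
            ds.attrs["channels"] = list(self.channels)


@dataclass
class ZonalKernel:
    """Real coefficients hhat_l^0 of a kernel depending on polar angle only."""

    coeffs: np.ndarray

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        if self.coeffs.size == 0:
            raise ValueError("kernel needs at least one coefficient")

    @property
    def n_coeff(self) -> int:
        return self.coeffs.size


def identity_kernel(n_coeff: int) -> ZonalKernel:
    """Kernel with hhat_l = (1/2pi)*sqrt((2l+1)/4pi): convolution is identity."""
    l = np.arange(n_coeff)
    return ZonalKernel(np.sqrt((2 * l + 1) / (4 * np.pi)) / (2 * np.pi))


# ---------------------------------------------------------------------------
# Complex basis matrices
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _complex_basis(b: int, grid_b: int) -> np.ndarray:
    """Matrix Y[(l,m), pixel] of harmonics l < b on the grid of bandwidth grid_b."""
    grid = make_grid(grid_b)
    beta = np.broadcast_to(grid.betas[None, :], (grid.n, grid.n)).ravel()
    alpha = np.broadcast_to(grid.alphas[:, None], (grid.n, grid.n)).ravel()
    ls = degrees_of_coeffs(b)
    ms = _orders_of_coeffs(b)
    return sph_harm_y(ls[:, None], ms[:, None], beta[None, :], alpha[None, :])


def sht_forward(smap: SphericalMap) -> SHCoeffs:
    """Quadrature forward transform at the grid's own bandwidth."""
    b = smap.grid.b
    Y = _complex_basis(b, b)
    w = smap.grid.area_weights.ravel()
    flat = smap.values.reshape(smap.n_channels, -1)
    coeffs = (flat * w) @ Y.conj().T
    return SHCoeffs(b=b, channels=smap.channels, values=coeffs)


def sht_inverse(coeffs: SHCoeffs, grid: SphericalGrid) -> SphericalMap:
    """Synthesis on `grid`; requires coeffs.b <= grid.b."""
    if coeffs.b > grid.b:
        raise ValueError(
            f"cannot synthesize bandwidth {coeffs.b} on a grid of bandwidth {grid.b}"
        )
    Y = _complex_basis(coeffs.b, grid.b)
    flat = coeffs.values @ Y
    if np.abs(flat.imag).max() > 1e-6 * max(1.0, np.abs(flat.real).max()):
        # coefficients without conjugate symmetry synthesize complex maps;
        # downstream carriers are real, so this is almost surely a bug
        raise ValueError("coefficients synthesize a non-real map")
    vals = flat.real.reshape(coeffs.values.shape[0], grid.n, grid.n)
    return SphericalMap(grid=grid, channels=coeffs.channels, values=vals)


def zonal_scale(b: int, kernel: ZonalKernel) -> np.ndarray:
    """Per-degree convolution factor 2*pi*sqrt(4*pi/(2l+1))*hhat_l, zero beyond."""
    l = np.arange(b)
    scale = np.zeros(b)
    nc = min(kernel.n_coeff, b)
    scale[:nc] = 2 * np.pi * np.sqrt(4 * np.pi / (2 * l[:nc] + 1)) * kernel.coeffs[:nc]
    return scale


def zonal_convolve(f: SHCoeffs, h: ZonalKernel) -> SHCoeffs:
    """Spherical convolution with a zonal kernel, diagonal in degree."""
    scale = zonal_scale(f.b, h)[degrees_of_coeffs(f.b)]
    return SHCoeffs(b=f.b, channels=f.channels, values=f.values * scale)


# ---------------------------------------------------------------------------
# Wigner rotations
# ---------------------------------------------------------------------------


def _log_fact(n: int) -> float:
    return lgamma(n + 1)


def wigner_d_matrix(l: int, beta: float) -> np.ndarray:
    """Little-d matrix d^l_{m'm}(beta), shape (2l+1, 2l+1), rows m'=-l..l."""
    d = np.zeros((2 * l + 1, 2 * l + 1))
    c, s = np.cos(beta / 2), np.sin(beta / 2)
    for mp in range(-l, l + 1):
        for m in range(-l, l + 1):
            pref = 0.5 * (
                _log_fact(l + mp) + _log_fact(l - mp) + _log_fact(l + m) + _log_fact(l - m)
            )
            kmin = max(0, m - mp)
            kmax = min(l + m, l - mp)
            val = 0.0
            for k in range(kmin, kmax + 1):
                pc = 2 * l + m - mp - 2 * k
                ps = mp - m + 2 * k
                if (c == 0.0 and pc > 0) or (s == 0.0 and ps > 0):
                    continue
                lognum = pref - (
                    _log_fact(l + m - k)
                    + _log_fact(k)
                    + _log_fact(l - mp - k)
                    + _log_fact(mp - m + k)
                )
                term = ((-1.0) ** (mp - m + k)) * np.exp(lognum)
                term *= (c**pc) * (s**ps)
                val += term
            d[mp + l, m + l] = val
    return d


def rotate_coeffs(f: SHCoeffs, R) -> SHCoeffs:
    """Coefficients of x -> f(R^-1 x) via per-degree Wigner-D blocks."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("R must be an orthogonal 3x3 matrix")
    if np.linalg.det(R) < 0:
        raise ValueError("R must be a proper rotation (det = +1)")
    import warnings

    with warnings.catch_warnings():
        # gimbal lock (beta ~ 0 or pi): any valid ZYZ split works here
        warnings.simplefilter("ignore", UserWarning)
        a, bb, c = Rotation.from_matrix(R).as_euler("ZYZ")
    out = np.empty_like(f.values)
    for l in range(f.b):
        sl = slice(coeff_index(l, -l), coeff_index(l, l) + 1)
        m = np.arange(-l, l + 1)
        D = (
            np.exp(-1j * m[:, None] * a)
            * wigner_d_matrix(l, bb)
            * np.exp(-1j * m[None, :] * c)
        )
        out[:, sl] = f.values[:, sl] @ D.T
    return SHCoeffs(b=f.b, channels=f.channels, values=out)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def pool_half(smap: SphericalMap) -> SphericalMap:
    """Area-weighted 2x2 mean pooling onto the grid of bandwidth b/2.

    The output grid carries the 2x2 block sums of the input area weights
    (a valid quadrature on the coarse nodes), so repeated pooling and
    global averaging telescope exactly.
    """
    b = smap.grid.b
    if b < 4:
        raise ValueError("pooling requires bandwidth >= 4")
    if b % 2 != 0:
        raise ValueError("pooling requires an even bandwidth")
    half = b  # output grid has n/2 = b samples per axis
    w = smap.grid.area_weights.reshape(half, 2, half, 2)
    v = smap.values.reshape(smap.n_channels, half, 2, half, 2)
    wsum = w.sum(axis=(1, 3))
    pooled = (v * w).sum(axis=(2, 4)) / wsum
    base = make_grid(b // 2)
    grid = SphericalGrid(
        b=b // 2, alphas=base.alphas, betas=base.betas, area_weights=wsum
    )
    return SphericalMap(grid=grid, channels=smap.channels, values=pooled)


def pool_half_truncate(smap: SphericalMap) -> SphericalMap:
    """Bandwidth halving by coefficient truncation (the spectral analogue).

    Unlike `pool_half`, this resamples the truncated band-limited function
    exactly on the coarse grid; spatial block pooling additionally smooths
    and slightly shifts in azimuth. Kept as the reference for tests.
    """
    b = smap.grid.b
    if b < 4 or b % 2:
        raise ValueError("pooling requires an even bandwidth >= 4")
    coeffs = sht_forward(smap)
    half = b // 2
    trunc = SHCoeffs(
        b=half, channels=coeffs.channels, values=coeffs.values[:, : half * half]
    )
    return sht_inverse(trunc, make_grid(half))


def global_pool(smap: SphericalMap) -> np.ndarray:
    """Area-weighted global average per channel."""
    w = smap.grid.area_weights
    return (smap.values * w).sum(axis=(1, 2)) / w.sum()


# ---------------------------------------------------------------------------
# Real-harmonics fast path (used by the network)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def real_transforms(b: int):
    """Real orthonormal-basis analysis/synthesis matrices on the grid of bandwidth b.

    Returns (A, S, l_of_k): analysis A (b^2, npix) with quadrature weights
    folded in, synthesis S (npix, b^2), and the degree of each coefficient.
    For band-limited maps, A @ S = identity and S @ A reproduces the samples.
    """
    Y = _complex_basis(b, b)  # (ncoef, npix), complex
    ls = degrees_of_coeffs(b)
    ms = _orders_of_coeffs(b)
    B = np.empty(Y.shape)
    sq2 = np.sqrt(2.0)
    for k in range(Y.shape[0]):
        m = ms[k]
        sgn = -1.0 if m % 2 else 1.0
        if m == 0:
            B[k] = Y[k].real
        elif m > 0:
            B[k] = sq2 * sgn * Y[k].real
        else:
            kpos = coeff_index(ls[k], -m)
            B[k] = sq2 * sgn * Y[kpos].imag
    w = make_grid(b).area_weights.ravel()
    A = B * w
    S = B.T.copy()
    return A, S, ls
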