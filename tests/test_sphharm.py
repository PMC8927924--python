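import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from trabstiff.egi import SphericalMap, make_grid, grid_directions
from trabstiff.sphharm import (
    SHCoeffs,
    ZonalKernel,
    coeff_index,
    degrees_of_coeffs,
    identity_kernel,
    global_pool,
    pool_half,
    real_transforms,
    rotate_coeffs,
    sht_forward,
    sht_inverse,
    zonal_convolve,
)


def random_bandlimited(b, rng, channels=1):
    """Random coefficients with the conjugate symmetry of a real map."""
    vals = np.zeros((channels, b * b), dtype=complex)
    for c in range(channels):
        for l in range(b):
            vals[c, coeff_index(l, 0)] = rng.standard_normal()
            for m in range(1, l + 1):
                z = rng.standard_normal() + 1j * rng.standard_normal()
                vals[c, coeff_index(l, m)] = z
                vals[c, coeff_index(l, -m)] = (-1) ** m * np.conj(z)
    return SHCoeffs(b=b, channels=tuple(f"c{i}" for i in range(channels)), values=vals)


class TestForwardTransform:
    def test_constant_map_hits_only_l0(self):
        grid = make_grid(8)
        smap = SphericalMap(grid=grid, channels=("x",), values=np.full((1, 16, 16), 2.5))
        coeffs = sht_forward(smap)
        assert coeffs.get(0, 0, 0) == pytest.approx(2.5 * np.sqrt(4 * np.pi), rel=1e-12)
        rest = np.abs(coeffs.values[0, 1:])
        assert rest.max() < 1e-12

    def test_single_harmonic_energy_isolated(self):
        grid = make_grid(8)
        beta = np.broadcast_to(grid.betas[None, :], (16, 16))
        alpha = np.broadcast_to(grid.alphas[:, None], (16, 16))
        vals = sph_harm_y(3, 2, beta, alpha).real[None]
        coeffs = sht_forward(SphericalMap(grid=grid, channels=("x",), values=vals))
        energy = coeffs.degree_energy()
        assert energy[3] > 0
        off = np.delete(energy, 3)
        assert off.max() < 1e-9 * energy[3]

    def test_round_trip_bandlimited(self, rng):
        grid = make_grid(16)
        f = sht_inverse(random_bandlimited(16, rng), grid)
        back = sht_inverse(sht_forward(f), grid)
        assert np.abs(back.values - f.values).max() < 1e-9

    def test_conjugate_symmetry_of_real_map(self, rng):
        grid = make_grid(8)
        smap = SphericalMap(grid=grid, channels=("x",), values=rng.random((1, 16, 16)))
        c = sht_forward(smap)
        for l in range(8):
            for m in range(1, l + 1):
                lhs = c.get(0, l, -m)
                rhs = (-1) ** m * np.conj(c.get(0, l, m))
                assert abs(lhs - rhs) < 1e-9

    def test_parseval(self, rng):
        grid = make_grid(16)
        coeffs = random_bandlimited(16, rng)
        f = sht_inverse(coeffs, grid)
        lhs = (grid.area_weights * f.values[0] ** 2).sum()
        rhs = (np.abs(coeffs.values) ** 2).sum()
        assert abs(lhs - rhs) < 1e-8 * max(1.0, rhs)


class TestInverseTransform:
    def test_zero_coeffs_zero_map(self):
        grid = make_grid(4)
        coeffs = SHCoeffs(b=4, channels=("x",), values=np.zeros((1, 16), complex))
        np.testing.assert_array_equal(sht_inverse(coeffs, grid).values, 0.0)

    def test_dc_coefficient_gives_ones(self):
        grid = make_grid(4)
        vals = np.zeros((1, 16), complex)
        vals[0, 0] = np.sqrt(4 * np.pi)
        out = sht_inverse(SHCoeffs(b=4, channels=("x",), values=vals), grid)
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-12)

    def test_linearity(self, rng):
        grid = make_grid(8)
        c1, c2 = random_bandlimited(8, rng), random_bandlimited(8, rng)
        comb = SHCoeffs(b=8, channels=("x",), values=2.5 * c1.values + c2.values)
        lhs = sht_inverse(comb, grid).values
        rhs = 2.5 * sht_inverse(c1, grid).values + sht_inverse(c2, grid).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_upward_bandwidth_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="bandwidth"):
            sht_inverse(random_bandlimited(8, rng), make_grid(4))

    def test_synthesis_on_finer_grid(self, rng):
        coeffs = random_bandlimited(4, rng)
        coarse = sht_inverse(coeffs, make_grid(4))
        fine = sht_inverse(coeffs, make_grid(8))
        # both sample the same band-limited function
        assert np.abs(sht_forward(fine).values[0, :16] - coeffs.values[0]).max() < 1e-9
        assert np.abs(sht_forward(coarse).values[0] - coeffs.values[0]).max() < 1e-9


class TestZonalConvolve:
    def test_identity_kernel(self, rng):
        f = random_bandlimited(8, rng)
        out = zonal_convolve(f, identity_kernel(8))
        np.testing.assert_allclose(out.values, f.values, atol=1e-12)

    def test_zero_kernel(self, rng):
        f = random_bandlimited(8, rng)
        out = zonal_convolve(f, ZonalKernel(np.zeros(8)))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_truncates_beyond_kernel_degrees(self, rng):
        f = random_bandlimited(8, rng)
        out = zonal_convolve(f, identity_kernel(3))
        ls = degrees_of_coeffs(8)
        assert np.abs(out.values[0][ls >= 3]).max() == 0.0
        np.testing.assert_allclose(out.values[0][ls < 3], f.values[0][ls < 3], atol=1e-12)

    def test_matches_spatial_quadrature_oracle(self, rng):
        # oracle: y(v) = 2*pi * sum_u f(u) h(angle(u, v)) w_u with the zonal
        # kernel synthesized from its own coefficients on a fine grid
        b = 8
        grid = make_grid(b)
        f = random_bandlimited(b, rng)
        fmap = sht_inverse(f, grid).values[0]
        hcoeffs = rng.standard_normal(b) * 0.3
        out = sht_inverse(zonal_convolve(f, ZonalKernel(hcoeffs)), grid).values[0]

        dirs = grid_directions(grid).reshape(-1, 3)
        w = grid.area_weights.ravel()
        # zonal kernel values as a function of cos(angle) via Legendre series
        from scipy.special import eval_legendre

        def hfun(ct):
            acc = np.zeros_like(ct)
            for l in range(b):
                nl = np.sqrt((2 * l + 1) / (4 * np.pi))
                acc += hcoeffs[l] * nl * eval_legendre(l, ct)
            return acc

        ct = np.clip(dirs @ dirs.T, -1, 1)
        oracle = 2 * np.pi * (hfun(ct) * (fmap.ravel() * w)[None, :]).sum(axis=1)
        np.testing.assert_allclose(out.ravel(), oracle, atol=1e-6)


class TestRotateCoeffs:
    def test_identity_rotation(self, rng):
        f = random_bandlimited(8, rng)
        out = rotate_coeffs(f, np.eye(3))
        np.testing.assert_allclose(out.values, f.values, atol=1e-12)

    def test_per_degree_norm_invariant(self, rng):
        f = random_bandlimited(16, rng)
        R = Rotation.random(random_state=5).as_matrix()
        out = rotate_coeffs(f, R)
        ls = degrees_of_coeffs(16)
        for l in range(16):
            n0 = np.linalg.norm(f.values[0][ls == l])
            n1 = np.linalg.norm(out.values[0][ls == l])
            assert abs(n0 - n1) < 1e-9 * max(1.0, n0)

    def test_z_rotation_phases(self, rng):
        f = random_bandlimited(8, rng)
        a0 = 0.613
        R = Rotation.from_euler("z", a0).as_matrix()
        out = rotate_coeffs(f, R)
        ms = np.concatenate([np.arange(-l, l + 1) for l in range(8)])
        np.testing.assert_allclose(
            out.values[0], f.values[0] * np.exp(-1j * ms * a0), atol=1e-12
        )

    def test_matches_pointwise_rotation_oracle(self, rng):
        # g(x) = f(R^-1 x) evaluated directly from the synthesis series
        b = 8
        grid = make_grid(b)
        f = random_bandlimited(b, rng)
        R = Rotation.random(random_state=11).as_matrix()
        g = sht_inverse(rotate_coeffs(f, R), grid).values[0].ravel()

        dirs = grid_directions(grid).reshape(-1, 3)
        x = dirs @ R  # rows are R^-1 applied to each direction
        beta = np.arccos(np.clip(x[:, 2], -1, 1))
        alpha = np.arctan2(x[:, 1], x[:, 0])
        ls = degrees_of_coeffs(b)
        ms = np.concatenate([np.arange(-l, l + 1) for l in range(b)])
        Y = sph_harm_y(ls[:, None], ms[:, None], beta[None, :], alpha[None, :])
        oracle = (f.values[0] @ Y).real
        np.testing.assert_allclose(g, oracle, atol=1e-9)

    def test_rejects_non_rotation(self, rng):
        f = random_bandlimited(4, rng)
        with pytest.raises(ValueError):
            rotate_coeffs(f, np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(ValueError):
            rotate_coeffs(f, np.eye(3) * 2)


class TestPooling:
    def test_constant_preserved(self):
        grid = make_grid(8)
        smap = SphericalMap(grid=grid, channels=("x",), values=np.full((1, 16, 16), 1.3))
        out = pool_half(smap)
        assert out.grid.b == 4
        np.testing.assert_allclose(out.values, 1.3, rtol=1e-12)

    def test_area_weighted_mean_preserved(self, rng):
        grid = make_grid(8)
        smap = SphericalMap(grid=grid, channels=("x",), values=rng.random((1, 16, 16)))
        before = global_pool(smap)
        after = global_pool(pool_half(smap))
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_truncation_pooling_matches_direct_coarse_sampling(self, rng):
        from trabstiff.sphharm import pool_half_truncate

        coeffs = random_bandlimited(4, rng)  # l < 4 = b/2
        fine = sht_inverse(coeffs, make_grid(8))
        pooled = pool_half_truncate(fine)
        direct = sht_inverse(coeffs, make_grid(4))
        assert np.abs(pooled.values - direct.values).max() < 1e-3

    def test_spatial_pooling_tracks_truncation_pooling(self, rng):
        # block averaging smooths: it agrees with the spectral reference at
        # low degrees up to its attenuation, not to quadrature precision
        from trabstiff.sphharm import pool_half_truncate

        coeffs = random_bandlimited(3, rng)
        fine = sht_inverse(coeffs, make_grid(16))
        a = pool_half(fine).values
        b = pool_half_truncate(fine).values
        scale = np.abs(b).max()
        assert np.abs(a - b).max() < 0.2 * scale

    def test_min_bandwidth(self):
        grid = make_grid(2)
        smap = SphericalMap(grid=grid, channels=("x",), values=np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            pool_half(smap)


class TestGlobalPool:
    def test_constant(self):
        grid = make_grid(4)
        smap = SphericalMap(
            grid=grid, channels=("a", "b"), values=np.stack([np.full((8, 8), 2.0), np.full((8, 8), -1.0)])
        )
        np.testing.assert_allclose(global_pool(smap), [2.0, -1.0], rtol=1e-12)

    def test_zero_mean_harmonic(self):
        grid = make_grid(8)
        vals = np.zeros((1, 16), complex)
        vals[0, coeff_index(1, 0)] = 1.0
        smap = sht_inverse(SHCoeffs(b=4, channels=("x",), values=vals), grid)
        assert abs(global_pool(smap)[0]) < 1e-9

    def test_alpha_shift_invariant(self, rng):
        grid = make_grid(8)
        vals = rng.random((1, 16, 16))
        a = global_pool(SphericalMap(grid=grid, channels=("x",), values=vals))
        b = global_pool(SphericalMap(grid=grid, channels=("x",), values=np.roll(vals, 5, axis=1)))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestEquivariance:
    def test_zonal_convolution_commutes_with_rotation(self, rng):
        b = 8
        f = random_bandlimited(b, rng)
        h = ZonalKernel(rng.standard_normal(b))
        grid = make_grid(b)
        for state in (0, 1):
            R = Rotation.random(random_state=state).as_matrix()
            lhs = sht_inverse(rotate_coeffs(zonal_convolve(f, h), R), grid).values
            rhs = sht_inverse(zonal_convolve(rotate_coeffs(f, R), h), grid).values
            assert np.abs(lhs - rhs).max() < 1e-8


class TestRealTransforms:
    def test_analysis_synthesis_identity(self, rng):
        for b in (4, 8):
            A, S, l_of_k = real_transforms(b)
            assert np.abs(A @ S - np.eye(b * b)).max() < 1e-12
            fh = rng.standard_normal(b * b)
            f = S @ fh
            assert np.abs(S @ (A @ f) - f).max() < 1e-11
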