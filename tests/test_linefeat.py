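"""Hessian analytics, eigenvalue ordering, and line-similarity behavior."""

import numpy as np
import pytest
from scipy.ndimage import rotate

from curviseg.iohub import GrayImage
from curviseg.linefeat import (
    eigvals2x2,
    hessian_at_scale,
    line_response,
    multiscale_response,
)


def _ridge(shape, row, profile_sd, amplitude=1.0):
    """Horizontal Gaussian-profile ridge centered at `row`."""
    r = np.arange(shape[0], dtype=float)[:, None]
    return amplitude * np.exp(-((r - row) ** 2) / (2 * profile_sd**2)) * np.ones((1, shape[1]))


class TestHessianAtScale:
    def test_constant_image_zero(self):
        h = hessian_at_scale(np.full((32, 32), 0.7), 2.0)
        for grid in (h.lxx, h.lxy, h.lyy):
            np.testing.assert_allclose(grid, 0.0, atol=1e-12)

    @pytest.mark.parametrize("s", [1.0, 2.0, 4.0])
    def test_quadratic_column_image(self, s):
        """I(r,c)=c**2 has analytic Lxx = 2 s^gamma, Lyy = 0 (gamma=2)."""
        H = W = 64
        _, c = np.mgrid[0:H, 0:W].astype(float)
        h = hessian_at_scale(c**2, s)
        m = int(4 * s) + 2
        sl = np.s_[m:-m, m:-m]
        np.testing.assert_allclose(h.lxx[sl], 2 * s**2, atol=1e-3)
        np.testing.assert_allclose(h.lyy[sl], 0.0, atol=1e-3)

    @pytest.mark.parametrize("s", [1.0, 2.0, 4.0])
    def test_bilinear_mixed_derivative(self, s):
        H = W = 64
        r, c = np.mgrid[0:H, 0:W].astype(float)
        h = hessian_at_scale(r * c, s)
        m = int(4 * s) + 2
        np.testing.assert_allclose(h.lxy[m:-m, m:-m], s**2, atol=1e-3)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            hessian_at_scale(np.zeros((8, 8)), 0.0)


class TestEigvals2x2:
    def test_diagonal(self):
        assert eigvals2x2(-2.0, 0.0, -0.1) == pytest.approx((-0.1, -2.0))

    def test_zero(self):
        assert eigvals2x2(0.0, 0.0, 0.0) == (0.0, 0.0)

    def test_symmetric_off_diagonal(self):
        # char poly of [[1,2],[2,1]]: l^2 - 2l - 3 -> roots -1, 3
        assert eigvals2x2(1.0, 2.0, 1.0) == pytest.approx((-1.0, 3.0))

    def test_equal_magnitude_tie_signed_ascending(self):
        assert eigvals2x2(3.0, 0.0, -3.0) == pytest.approx((-3.0, 3.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numpy_eigvalsh(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=3)
        ours = eigvals2x2(a, b, c)
        ref = np.linalg.eigvalsh([[a, b], [b, c]])
        assert sorted(ours) == pytest.approx(sorted(ref))
        assert abs(ours[0]) <= abs(ours[1]) + 1e-12


class TestLineResponse:
    def test_wrong_sign_suppressed(self):
        assert line_response(1.0, 5.0, polarity="bright") == 0.0

    def test_pure_line_saturated(self):
        v = line_response(0.0, -10.0, beta_r=0.5, c_r=1.0)
        assert v == pytest.approx(1 - np.exp(-50), abs=1e-9)

    def test_isotropic_blob_damped(self):
        v = line_response(-1.0, -1.0, beta_r=0.5, c_r=1.0)
        assert v == pytest.approx(np.exp(-2) * (1 - np.exp(-1)), abs=1e-7)
        assert v == pytest.approx(0.0855482, abs=1e-6)

    def test_dark_polarity_flips(self):
        assert line_response(0.0, -10.0, polarity="dark") == 0.0
        assert line_response(0.0, 10.0, polarity="dark") > 0.9

    def test_range_property(self):
        rng = np.random.default_rng(0)
        l1 = rng.normal(0, 10, 1000)
        l2 = rng.normal(0, 10, 1000)
        v = line_response(l1, l2, beta_r=0.5, c_r=2.0)
        assert np.all((v >= 0) & (v <= 1))


class TestMultiscaleResponse:
    def test_constant_image_zero(self):
        fm = multiscale_response(np.full((24, 24), 0.3), [1.0, 2.0])
        np.testing.assert_array_equal(fm.v, 0.0)

    def test_superset_grid_dominates(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        v1 = multiscale_response(img, [1.0], c_r=0.5).v
        v2 = multiscale_response(img, [1.0, 2.0], c_r=0.5).v
        assert np.all(v2 >= v1 - 1e-12)

    @pytest.mark.parametrize("profile_sd", [2.0])
    def test_centerline_scale_matches_dense_argmax(self, profile_sd):
        """Argmax over the working grid lands within one grid step of a
        dense 50-point brute-force argmax on a ridge centerline."""
        img = _ridge((64, 64), row=32, profile_sd=profile_sd)
        grid = (1.0, 1.5, 2.0, 3.0, 4.0)
        fm = multiscale_response(img, grid, c_r=0.05)
        picked = grid[int(fm.best_scale_idx[32, 40])]

        dense = np.linspace(0.5, 6.0, 50)
        responses = [
            multiscale_response(img, [s], c_r=0.05).v[32, 40] for s in dense
        ]
        s_star = dense[int(np.argmax(responses))]
        idx = int(np.searchsorted(grid, picked))
        neighborhood = grid[max(0, idx - 1): idx + 2]
        assert neighborhood[0] - 0.26 <= s_star <= neighborhood[-1] + 0.26

    def test_wider_ridge_selects_larger_scale(self):
        """On a two-ridge phantom the wider ridge's centerline best scale
        exceeds the thin ridge's (scale tracks structure width)."""
        img = np.zeros((80, 80))
        img += _ridge((80, 80), row=20, profile_sd=0.8)
        img += _ridge((80, 80), row=60, profile_sd=3.0)
        fm = multiscale_response(img, (1.0, 2.0, 3.0, 4.0, 6.0, 8.0), c_r=0.1)
        s_thin = fm.scales[int(fm.best_scale_idx[20, 40])]
        s_wide = fm.scales[int(fm.best_scale_idx[60, 40])]
        assert s_wide > s_thin

    def test_rotation_90_exact(self):
        rng = np.random.default_rng(2)
        img = rng.random((48, 48))
        fm = multiscale_response(img, [1.0, 2.0], c_r=0.5)
        fm_rot = multiscale_response(np.rot90(img), [1.0, 2.0], c_r=0.5)
        np.testing.assert_allclose(fm_rot.v, np.rot90(fm.v), atol=1e-10)

    def test_rotation_45_quasi_invariance(self):
        """Interpolated 45-degree rotation changes the response by at most
        0.05 mean absolute difference."""
        img = _ridge((96, 96), row=48, profile_sd=2.0)
        rot = rotate(img, 45.0, reshape=False, order=3, mode="reflect")
        v0 = multiscale_response(img, (1.0, 2.0, 3.0, 4.0), c_r=0.05).v
        v45 = multiscale_response(rot, (1.0, 2.0, 3.0, 4.0), c_r=0.05).v
        v0_rot = rotate(v0, 45.0, reshape=False, order=1, mode="constant")
        inner = np.s_[28:-28, 28:-28]  # ignore rotation fill-in near borders
        assert np.mean(np.abs(v45[inner] - v0_rot[inner])) <= 0.05

    def test_feature_map_on_gray_image_normalized(self):
        img = GrayImage(np.tile(np.array([0, 0, 200, 0, 0], dtype=np.uint8), (5, 1)).T)
        fm = multiscale_response(img, (1.0, 2.0))
        assert fm.v.max() <= 1.0 and fm.v.min() >= 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            multiscale_response(np.zeros((8, 8)), [])
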