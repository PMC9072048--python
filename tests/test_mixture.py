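"""Mixture density, histogram-weighted EM, and likelihood energies."""

import numpy as np
import pytest
from scipy import stats

from curviseg.iohub import GrayImage, Histogram, compute_histogram
from curviseg.mixture import (
    E_MAX,
    P_FLOOR,
    ComponentSpec,
    MixtureParams,
    fit_em,
    likelihood_energy,
    mixture_pdf,
)

from helpers import per_pixel_em_step, sample_mixture_hist


def _params(weights, sigma_r, means, sds, classes):
    return MixtureParams(
        weights=np.asarray(weights, float),
        rayleigh_sigma=sigma_r,
        gauss_means=np.asarray(means, float),
        gauss_sds=np.asarray(sds, float),
        classes=classes,
    )


class TestMixturePdf:
    def test_single_gaussian_peak(self):
        p = _params([1.0 - 1e-12, 1e-12], None, [100.0, 200.0], [10.0, 10.0],
                    ("background", "target"))
        # weight mass essentially on the first component
        assert mixture_pdf(100, p) == pytest.approx(1 / (10 * np.sqrt(2 * np.pi)), rel=1e-6)

    def test_rayleigh_zero_at_origin(self):
        p = _params([1.0 - 1e-12, 1e-12], 30.0, [200.0], [10.0], ("background", "target"))
        assert mixture_pdf(0, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_gaussians_at_one_sd(self):
        p = _params([0.5, 0.5], None, [90.0, 110.0], [10.0, 10.0],
                    ("background", "target"))
        assert mixture_pdf(100, p) == pytest.approx(0.0241971, abs=1e-6)

    def test_matches_scipy_densities(self):
        """Component densities agree with scipy.stats rayleigh/norm."""
        p = _params([0.4, 0.35, 0.25], 20.0, [120.0, 200.0], [15.0, 12.0],
                    ("background", "background", "target"))
        t = np.arange(256, dtype=float)
        expected = (
            0.4 * stats.rayleigh.pdf(t, scale=20.0)
            + 0.35 * stats.norm.pdf(t, 120.0, 15.0)
            + 0.25 * stats.norm.pdf(t, 200.0, 12.0)
        )
        np.testing.assert_allclose(mixture_pdf(t, p), expected, rtol=1e-12)

    def test_discrete_mass_near_one(self):
        """Summing the density over in-range gray levels captures ~all mass."""
        p = _params([0.3, 0.4, 0.3], 25.0, [110.0, 190.0], [14.0, 11.0],
                    ("background", "background", "target"))
        total = np.sum(mixture_pdf(np.arange(256, dtype=float), p))
        assert 0.98 <= total <= 1.005

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _params([0.5, 0.4], None, [90.0, 110.0], [10.0, 10.0],
                    ("background", "target"))


class TestFitEM:
    def test_single_gaussian_closed_form(self):
        """A one-Gaussian fit lands on the histogram mean/variance after a
        single iteration (responsibilities are identically 1)."""
        rng = np.random.default_rng(5)
        img = GrayImage(rng.integers(40, 200, size=(32, 32), dtype=np.uint8))
        hist = compute_histogram(img)
        res = fit_em(hist, ComponentSpec(0, 0, 1), max_iter=1)
        assert res.params.gauss_means[0] == pytest.approx(hist.mean(), abs=1e-9)
        assert res.params.gauss_sds[0] == pytest.approx(np.sqrt(hist.var()), abs=1e-9)

    def test_two_component_recovery(self):
        """Known 0.5 Rayleigh(30) + 0.5 Gaussian(180, 12) mixture, large n."""
        hist, _ = sample_mixture_hist([0.5, 0.5], 30.0, [180.0], [12.0], 10**6, seed=1)
        res = fit_em(hist, ComponentSpec(1, 0, 1), seed=1)
        p = res.params
        assert abs(p.weights[0] - 0.5) <= 0.03 and abs(p.weights[1] - 0.5) <= 0.03
        assert abs(p.gauss_means[0] - 180.0) <= 2.0
        assert abs(p.rayleigh_sigma - 30.0) <= 2.0

    def test_loglik_trace_non_decreasing(self):
        hist, _ = sample_mixture_hist([0.5, 0.5], 30.0, [180.0], [12.0], 10**5, seed=2)
        res = fit_em(hist, ComponentSpec(1, 0, 1), seed=2)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-9 * np.abs(res.loglik_trace[:-1]))

    def test_deterministic_given_seed(self):
        hist, _ = sample_mixture_hist(
            [0.3, 0.3, 0.2, 0.2], 20.0, [90.0, 140.0, 200.0], [10.0, 12.0, 10.0],
            10**5, seed=3,
        )
        a = fit_em(hist, seed=7)
        b = fit_em(hist, seed=7)
        np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)
        np.testing.assert_array_equal(a.params.weights, b.params.weights)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_histogram_em_equals_per_pixel_oracle(self, seed):
        """Histogram-weighted updates coincide with naive per-pixel EM on a
        16x16 image (same initialization, iteration by iteration), up to
        floating-point accumulation order."""
        rng = np.random.default_rng(seed)
        px = np.clip(
            np.concatenate([
                rng.rayleigh(25.0, 128),
                rng.normal(150.0, 15.0, 128),
            ]).round(), 0, 255,
        ).astype(np.uint8)
        rng.shuffle(px)
        img = GrayImage(px.reshape(16, 16))
        hist = compute_histogram(img)

        from curviseg.mixture import _init_params
        spec = ComponentSpec(1, 0, 1)
        w, sr, mu, sd = _init_params(hist, spec, np.random.default_rng(seed))
        for _ in range(8):
            w, sr, mu, sd = per_pixel_em_step(img.pixels, w, sr, mu, sd)

        res = fit_em(hist, spec, tol=0.0, max_iter=8, seed=seed)
        p = res.params
        np.testing.assert_allclose(p.weights, w, rtol=1e-9, atol=1e-12)
        assert p.rayleigh_sigma == pytest.approx(sr, rel=1e-9)
        np.testing.assert_allclose(p.gauss_means, mu, rtol=1e-9)
        np.testing.assert_allclose(p.gauss_sds, sd, rtol=1e-9)

    def test_degenerate_histogram_rejected(self):
        h = Histogram(np.eye(1, 256, 7, dtype=int)[0] * 100, 100)
        with pytest.raises(ValueError, match="degenerate"):
            fit_em(h)


class TestLikelihoodEnergy:
    def _fitted(self):
        return _params([0.4, 0.35, 0.25], 20.0, [120.0, 200.0], [15.0, 12.0],
                       ("background", "background", "target"))

    def test_energy_is_neg_log_of_class_conditional(self):
        """e_bg/e_fg equal -ln p(x|class) with scipy densities as the
        independent route (background renormalized among its components)."""
        p = self._fitted()
        img = GrayImage(np.array([[10, 120, 200]] * 3, dtype=np.uint8))
        e = likelihood_energy(img, p)
        t = img.pixels.astype(float)
        w_bg = np.array([0.4, 0.35]) / 0.75
        p_bg = w_bg[0] * stats.rayleigh.pdf(t, scale=20.0) + w_bg[1] * stats.norm.pdf(t, 120.0, 15.0)
        p_fg = stats.norm.pdf(t, 200.0, 12.0)
        np.testing.assert_allclose(e.e_bg, -np.log(np.maximum(p_bg, P_FLOOR)), rtol=1e-12)
        np.testing.assert_allclose(e.e_fg, -np.log(np.maximum(p_fg, P_FLOOR)), rtol=1e-12)

    def test_energy_clamped_at_e_max(self):
        """Gray levels impossibly far from the target hit exactly
        -ln(1e-12) = 27.6310."""
        p = self._fitted()
        img = GrayImage(np.zeros((3, 3), dtype=np.uint8))  # level 0, p_fg ~ 0
        e = likelihood_energy(img, p)
        assert e.e_fg[0, 0] == pytest.approx(E_MAX, abs=1e-4)
        assert E_MAX == pytest.approx(27.6310, abs=1e-4)
        assert np.all(e.e_bg >= 0) and np.all(e.e_fg <= E_MAX + 1e-12)

    def test_probability_levels_map_to_expected_energies(self):
        assert -np.log(0.1) == pytest.approx(2.302585, abs=1e-6)
        p = self._fitted()
        img = GrayImage(np.full((3, 3), 200, dtype=np.uint8))
        e = likelihood_energy(img, p)
        # at the target mean the conditional density is the normal peak
        assert e.e_fg[0, 0] == pytest.approx(-np.log(stats.norm.pdf(0) / 12.0), rel=1e-9)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        p = _params([0.4, 0.35, 0.25], 20.0, [120.0, 200.0], [15.0, 12.0],
                    ("background", "background", "target"))
        f = tmp_path / "params.json"
        p.to_json(f)
        back = MixtureParams.from_json(f)
        np.testing.assert_allclose(back.weights, p.weights)
        assert back.rayleigh_sigma == p.rayleigh_sigma
        assert back.classes == p.classes
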