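"""Contrast-statistics front-end: filters, Weibull fits, CE/SC indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sceneddm.scene_stats import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    compute_local_contrast,
    compute_scene_stats,
    fit_weibull,
    to_luminance,
    weibull_shape_from_cv,
)
from sceneddm.synth import TextureParams, generate_texture


class TestToLuminance:
    def test_white_and_black(self):
        white = np.ones((32, 32, 3))
        black = np.zeros((32, 32, 3))
        assert np.allclose(to_luminance(white), 1.0)
        assert np.allclose(to_luminance(black), 0.0)

    def test_green_brighter_than_red(self):
        red = np.zeros((32, 32, 3)); red[..., 0] = 1.0
        green = np.zeros((32, 32, 3)); green[..., 1] = 1.0
        assert to_luminance(green).mean() > to_luminance(red).mean()

    def test_integer_input_rescaled(self):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        assert np.allclose(to_luminance(img), 1.0)

    def test_wrong_channel_count(self):
        with pytest.raises(FormatError):
            to_luminance(np.zeros((32, 32, 2)))


class TestLocalContrast:
    def test_constant_image_zero_contrast(self):
        cmap = compute_local_contrast(np.full((64, 64), 0.3), scales=(1, 2, 4))
        for plane in cmap.planes:
            assert np.all(plane == 0.0)

    def test_step_edge_peaks_at_edge_column(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        cmap = compute_local_contrast(img, scales=(2.0,))
        b = cmap.border[0]
        interior = cmap.planes[0][b:-b]
        argmax = interior.argmax(axis=1)
        assert np.all(np.isin(argmax, (31, 32)))

    def test_gaussian_noise_magnitudes_are_rayleigh(self):
        """White noise through the filter pair gives Rayleigh moduli.

        Pixels are strided to decorrelate the samples before the KS test.
        """
        mags = []
        for s in range(14):
            rng = np.random.default_rng(s)
            img = np.clip(0.5 + 0.1 * rng.standard_normal((512, 512)), 0, 1)
            cmap = compute_local_contrast(img, scales=(1.0,))
            b = cmap.border[0]
            mags.append(cmap.planes[0][b:-b, b:-b][::6, ::6].ravel())
        mags = np.concatenate(mags)
        assert mags.size >= 1e5
        sigma = np.sqrt(np.mean(mags**2) / 2)
        ks = stats.kstest(mags, lambda x: stats.rayleigh.cdf(x, scale=sigma))
        assert ks.pvalue > 0.01

    def test_scale_too_large_rejected(self):
        with pytest.raises(ParameterError):
            compute_local_contrast(np.full((64, 64), 0.5), scales=(20.0,))

    def test_image_validation(self):
        with pytest.raises(FormatError):
            compute_local_contrast(np.full((16, 16), 0.5))  # too small
        with pytest.raises(FormatError):
            compute_local_contrast(np.full((64, 64), 1.5))  # out of range


class TestFitWeibull:
    @pytest.mark.parametrize(
        "draw, expected_gamma",
        [("exponential", 1.0), ("rayleigh", 2.0)],
        ids=["exponential-is-shape-1", "rayleigh-is-shape-2"],
    )
    def test_analytic_special_cases(self, draw, expected_gamma):
        rng = np.random.default_rng(11)
        x = getattr(rng, draw)(1.0, 100_000)
        params = fit_weibull(x)
        assert params.gamma == pytest.approx(expected_gamma, rel=0.02)
        if draw == "exponential":
            assert params.beta == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("gamma_true", [0.6, 1.3, 2.5])
    def test_matches_grid_search_oracle(self, gamma_true):
        """The profile-likelihood root agrees with brute-force grid ML."""
        rng = np.random.default_rng(int(gamma_true * 10))
        x = rng.weibull(gamma_true, 5000) * 0.05
        fitp = fit_weibull(x)
        lb = np.linspace(np.log(fitp.beta) - 0.5, np.log(fitp.beta) + 0.5, 200)
        lg = np.linspace(np.log(fitp.gamma) - 0.5, np.log(fitp.gamma) + 0.5, 200)
        lx = np.log(x)
        n = x.size
        best, b_best, g_best = -np.inf, None, None
        for g in np.exp(lg):
            xg_sum = (x**g).sum()
            for b in np.exp(lb):
                ll = n * np.log(g) - n * g * np.log(b) + (g - 1) * lx.sum() - xg_sum / b**g
                if ll > best:
                    best, b_best, g_best = ll, b, g
        step_b, step_g = lb[1] - lb[0], lg[1] - lg[0]
        assert abs(np.log(fitp.beta) - np.log(b_best)) <= step_b
        assert abs(np.log(fitp.gamma) - np.log(g_best)) <= step_g

    def test_matches_scipy_reference(self):
        x = np.random.default_rng(4).weibull(1.7, 20_000) * 0.3
        params = fit_weibull(x)
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        assert params.gamma == pytest.approx(c, rel=1e-3)
        assert params.beta == pytest.approx(scale, rel=1e-3)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            fit_weibull(np.zeros(1000))
        with pytest.raises(DegenerateInputError):
            fit_weibull(np.full(1000, 0.7))
        with pytest.raises(DegenerateInputError):
            fit_weibull(np.random.default_rng(0).exponential(1, 50))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        k=st.floats(min_value=0.5, max_value=4.0),
        gamma=st.floats(min_value=0.5, max_value=3.0),
    )
    def test_scale_equivariance(self, k, gamma):
        """Multiplying samples by k scales beta by k and leaves gamma alone."""
        x = np.random.default_rng(99).weibull(gamma, 2000)
        p1 = fit_weibull(x)
        p2 = fit_weibull(k * x)
        assert p2.gamma == pytest.approx(p1.gamma, rel=1e-6)
        assert p2.beta == pytest.approx(k * p1.beta, rel=1e-6)


class TestSceneStats:
    def test_contrast_scaling_moves_ce_not_sc(self):
        base = generate_texture(TextureParams(n_elements=300, seed=2, shape=(96, 96)))
        mid = 0.5 + (base - 0.5) * 0.45  # headroom for scaling without clipping
        s1 = compute_scene_stats(mid, scales=(1, 2, 4))
        scaled = 0.5 + (mid - 0.5) * 2.0
        s2 = compute_scene_stats(scaled, scales=(1, 2, 4))
        assert s2.CE == pytest.approx(2.0 * s1.CE, rel=0.01)
        assert s2.SC == pytest.approx(s1.SC, rel=0.01)

    def test_sparse_below_dense(self):
        sparse = generate_texture(TextureParams(n_elements=10, seed=0, shape=(96, 96)))
        dense = generate_texture(TextureParams(n_elements=5000, seed=0, shape=(96, 96)))
        s_sparse = compute_scene_stats(sparse, scales=(1, 2, 4))
        s_dense = compute_scene_stats(dense, scales=(1, 2, 4))
        assert s_sparse.SC < s_dense.SC

    def test_noise_image_sc_near_two(self):
        img = np.clip(0.5 + 0.12 * np.random.default_rng(1).standard_normal((256, 256)),
                      0, 1)
        s = compute_scene_stats(img, scales=(1, 2, 4))
        assert s.SC == pytest.approx(2.0, abs=0.1)

    def test_clutter_monotonicity(self):
        """SC increases with the generator clutter level (rank correlation)."""
        levels = (10, 50, 250, 1000, 5000)
        rows = []
        for lvl in levels:
            for s in range(8):
                img = generate_texture(
                    TextureParams(n_elements=lvl, seed=100 + s, shape=(96, 96))
                )
                rows.append((lvl, compute_scene_stats(img, scales=(1, 2, 4)).SC))
        lvls, scs = zip(*rows)
        rho = stats.spearmanr(lvls, scs).statistic
        assert rho >= 0.95

    def test_routes_agree_in_rank(self):
        """Moment-proxy route tracks the ML route across the clutter axis."""
        rng = np.random.default_rng(8)
        ce_w, sc_w, ce_l, sc_l = [], [], [], []
        for i in range(50):
            n_el = int(np.exp(rng.uniform(np.log(10), np.log(5000))))
            img = generate_texture(TextureParams(
                n_elements=n_el, amplitude_scale=float(rng.uniform(0.04, 0.16)),
                seed=int(rng.integers(2**31 - 1)), shape=(96, 96),
            ))
            w = compute_scene_stats(img, scales=(1, 2, 4), route="weibull")
            l = compute_scene_stats(img, scales=(1, 2, 4), route="lgn")
            ce_w.append(w.CE); sc_w.append(w.SC); ce_l.append(l.CE); sc_l.append(l.SC)
        assert stats.spearmanr(ce_w, ce_l).statistic >= 0.9
        assert stats.spearmanr(sc_w, sc_l).statistic >= 0.9

    def test_deterministic(self):
        img = generate_texture(TextureParams(n_elements=200, seed=5, shape=(96, 96)))
        s1 = compute_scene_stats(img, scales=(1, 2))
        s2 = compute_scene_stats(img.copy(), scales=(1, 2))
        assert (s1.CE, s1.SC) == (s2.CE, s2.SC)

    def test_cv_inversion_roundtrip(self):
        for gamma in (0.7, 1.0, 2.0, 3.5):
            cv = np.sqrt(
                stats.weibull_min.var(gamma)
            ) / stats.weibull_min.mean(gamma)
            assert weibull_shape_from_cv(cv) == pytest.approx(gamma, rel=1e-6)
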