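"""Detrending methods: spline projection and the SPM/PPF/EMD baselines."""

import numpy as np
import pytest

from splinedetrend.detrend import (
    choose_resampling,
    emd_detrend,
    emd_sift,
    ppf_detrend,
    spline_detrend,
    spm_detrend,
    spm_lambda_for_cutoff,
)


class TestChooseResampling:
    def test_integer_arithmetic(self):
        c = choose_resampling(1000.0, 4.0, 10001)
        assert (c.m, c.M) == (250, 41)
        c = choose_resampling(10000.0, 4.0, 100001)
        assert (c.m, c.M) == (2500, 41)

    def test_realized_frequency_reported(self):
        c = choose_resampling(1000.0, 3.0, 5000)
        assert c.realized_fr == pytest.approx(1000.0 / c.m)

    @pytest.mark.parametrize("fr", [600.0, 500.0, 0.0, -1.0])
    def test_invalid_fr_rejected(self, fr):
        with pytest.raises(ValueError):
            choose_resampling(1000.0, fr, 5000)


class TestSplineDetrend:
    def test_coarse_space_member_has_tiny_residual(self, rng):
        from splinedetrend.bspline_core import indirect_transform
        m = 250
        c = rng.normal(size=17)
        g = indirect_transform(c, 3, m, (17 - 1) * m + 1)
        res = spline_detrend(g, 1000.0, 4.0)
        assert np.sum(res.residual ** 2) < 1e-16 * np.sum(g ** 2) + 1e-20

    def test_out_of_band_sinusoid_recovery(self):
        fs, fr = 1000.0, 4.0
        t = np.arange(0, 20, 1 / fs)
        trend = 0.8 * np.sin(2 * np.pi * 0.7 * t)
        hf = 0.5 * np.sin(2 * np.pi * 50.0 * t)
        res = spline_detrend(trend + hf, fs, fr)
        sl = slice(2000, -2000)
        nm = np.mean((res.trend - trend)[sl] ** 2) / np.mean(trend[sl] ** 2)
        assert nm < 0.05

    def test_high_frequency_passthrough(self):
        fs, fr = 1000.0, 4.0
        t = np.arange(0, 20, 1 / fs)
        hf = np.sin(2 * np.pi * 40.0 * t)  # 10 x f_r
        res = spline_detrend(hf, fs, fr)
        sl = slice(2000, -2000)
        ratio = np.sqrt(np.mean(res.residual[sl] ** 2) / np.mean(hf[sl] ** 2))
        assert abs(ratio - 1.0) < 0.05

    def test_zero_signal(self):
        res = spline_detrend(np.zeros(5000), 1000.0, 4.0)
        assert np.allclose(res.trend, 0) and np.allclose(res.residual, 0)

    def test_linearity(self, rng):
        fs, fr = 1000.0, 4.0
        x, y = rng.normal(size=4000), rng.normal(size=4000)
        lhs = spline_detrend(2.0 * x + 0.5 * y, fs, fr).trend
        rhs = 2.0 * spline_detrend(x, fs, fr).trend + 0.5 * spline_detrend(y, fs, fr).trend
        assert np.abs(lhs - rhs).max() < 1e-10


class TestSpmDetrend:
    def test_small_lambda_interpolates(self, rng):
        g = rng.normal(size=400)
        res = spm_detrend(g, 1e-8, 4)
        assert np.abs(res.trend - g).max() < 1e-5

    def test_large_lambda_approaches_blockwise_line_fit(self, rng):
        g = rng.normal(size=200)
        res = spm_detrend(g, 1e7, 2)
        for a, b in ((0, 100), (100, 200)):
            x = np.arange(b - a, dtype=float)
            line = np.polyval(np.polyfit(x, g[a:b], 1), x)
            assert np.abs(res.trend[a:b] - line).max() < 1e-3

    def test_constant_signal_reproduced(self):
        res = spm_detrend(np.full(300, 2.5), 100.0, 3)
        assert np.allclose(res.trend, 2.5, atol=1e-10)

    def test_lambda_cutoff_mapping_monotone(self):
        l4 = spm_lambda_for_cutoff(1000.0, 4.0)
        l8 = spm_lambda_for_cutoff(1000.0, 8.0)
        assert l4 > l8 > 0


class TestPpfDetrend:
    def test_blockwise_quadratic_reproduced(self):
        t = np.arange(100, dtype=float)
        g = 0.3 * t**2 - t + 2.0  # quadratic globally, hence per block
        res = ppf_detrend(g, 5, 2)
        assert np.abs(res.residual).max() < 1e-8

    def test_constant_signal(self):
        res = ppf_detrend(np.full(100, 4.0), 10, 2)
        assert np.abs(res.residual).max() < 1e-10

    def test_matches_polyfit_oracle_per_block(self, rng):
        g = rng.normal(size=120)
        res = ppf_detrend(g, 6, 2)
        for k in range(6):
            a, b = 20 * k, 20 * (k + 1)
            x = np.arange(20, dtype=float)
            fit = np.polyval(np.polyfit(x, g[a:b], 2), x)
            assert np.abs(res.trend[a:b] - fit).max() < 1e-8

    def test_too_short_subintervals_rejected(self):
        with pytest.raises(ValueError):
            ppf_detrend(np.zeros(10), 5, 2)


class TestEmdDetrend:
    def test_monotone_signal_is_all_trend(self):
        g = np.linspace(0, 5, 200) ** 1.5
        res = emd_detrend(g, 100.0, 1.0)
        assert np.allclose(res.trend, g)
        assert np.allclose(res.residual, 0.0)

    def test_pure_tone_above_cutoff_leaves_no_trend(self):
        fs = 1000.0
        t = np.arange(0, 4, 1 / fs)
        g = np.sin(2 * np.pi * 50.0 * t)
        res = emd_detrend(g, fs, 4.0)
        assert np.sum(res.trend ** 2) < 0.01 * np.sum(g ** 2)

    def test_sifting_reconstruction_is_complete(self, rng):
        g = np.cumsum(rng.normal(size=2000)) * 0.01 + rng.normal(size=2000)
        imfs, residue = emd_sift(g)
        rec = residue + np.sum(imfs, axis=0) if imfs else residue
        assert np.abs(rec - g).max() < 1e-8

    def test_separates_slow_trend_from_fast_tone(self):
        fs = 500.0
        t = np.arange(0, 8, 1 / fs)
        slow = np.sin(2 * np.pi * 0.3 * t)
        fast = 0.4 * np.sin(2 * np.pi * 30.0 * t)
        res = emd_detrend(slow + fast, fs, 2.0)
        assert np.mean((res.trend - slow) ** 2) / np.mean(slow ** 2) < 0.05


@pytest.mark.parametrize("method", ["spline", "spm", "ppf", "emd"])
def test_trend_plus_residual_reconstructs_input(method, short_recording):
    cfg, rec, _ = short_recording
    x = rec.ap
    if method == "spline":
        res = spline_detrend(x, cfg.f_s, 4.0)
    elif method == "spm":
        res = spm_detrend(x, spm_lambda_for_cutoff(cfg.f_s, 4.0), 250)
    elif method == "ppf":
        res = ppf_detrend(x, 1250, 2)
    else:
        res = emd_detrend(x, cfg.f_s, 2.0)
    assert np.abs(res.trend + res.residual - x).max() < 1e-12
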