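"""Unit and property tests of the timescale metrics."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timescales import (
    TimeSeriesMatrix,
    ZeroVarianceError,
    acf_with_acw,
    acw,
    bandpass,
    median_frequency,
    metric_map,
    sample_acf,
)

from conftest import acf_double_loop

TR = 2.16


class TestSampleAcf:
    def test_alternating_series_lag_one(self):
        # x = +1, -1, ... has mean 0; hand evaluation gives r[1] = -(N-1)/N
        x = np.array([1.0, -1.0] * 4)
        res = sample_acf(x)
        assert res.r[1] == pytest.approx(-7 / 8, abs=1e-14)

    def test_lag_zero_is_one_exactly(self, rng):
        res = sample_acf(rng.standard_normal(64))
        assert res.r[0] == 1.0

    def test_constant_series_raises(self):
        with pytest.raises(ZeroVarianceError, match="zero variance"):
            sample_acf(np.array([5.0, 5.0, 5.0, 5.0]))

    def test_max_lag_out_of_range(self, rng):
        x = rng.standard_normal(16)
        with pytest.raises(ValueError):
            sample_acf(x, max_lag=16)
        with pytest.raises(ValueError):
            sample_acf(x, max_lag=0)

    @pytest.mark.parametrize("n", [8, 33, 145, 512])
    def test_matches_double_loop_oracle(self, n, rng):
        x = rng.standard_normal(n)
        max_lag = n - 2
        expected = acf_double_loop(x, max_lag)
        got = sample_acf(x, max_lag=max_lag).r
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    @given(st.integers(0, 2**32 - 1), st.integers(8, 200))
    @settings(max_examples=25, deadline=None)
    def test_bounded_and_normalised(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        r = sample_acf(x).r
        assert r[0] == 1.0
        assert np.all(np.abs(r) <= 1 + 1e-12)

    def test_scale_and_offset_invariance(self, rng):
        x = rng.standard_normal(100)
        r1 = sample_acf(x).r
        r2 = sample_acf(-3.7 * x + 11.0).r
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestAcw:
    def test_sinusoid_quarter_period(self):
        # the ACF of a sinusoid is a cosine: first zero at T/4
        for period in (20, 40, 100):
            x = np.sin(2 * np.pi * np.arange(10 * period) / period)
            res = acf_with_acw(x, dt=1.0)
            assert abs(res.acw0 - period / 4) <= 1.0
            assert res.acw50 <= res.acw0

    def test_first_lag_at_or_below_threshold(self):
        r = np.array([1.0, 0.6, 0.4, 0.1])
        assert acw(r, 0.5, dt=TR) == pytest.approx(2 * TR)

    def test_not_reached_sentinel(self, caplog):
        r = np.array([1.0, 0.9, 0.8, 0.7])
        with caplog.at_level(logging.WARNING):
            out = acw(r, 0.0, dt=1.0)
        assert np.isnan(out)
        assert "not reached" in caplog.text

    def test_acw0_at_least_dt(self, rng):
        res = acf_with_acw(rng.standard_normal(50), dt=TR)
        assert res.acw0 >= TR


class TestMedianFrequency:
    def test_pure_sine_hits_its_bin(self):
        n, f0 = 1024, 0.10
        x = np.sin(2 * np.pi * f0 * np.arange(n) * TR)
        res = median_frequency(x, TR)
        assert abs(res.mf - f0) <= 1 / (n * TR)

    def test_two_sine_tie_resolves_to_lower(self):
        # equal power at 0.05 and 0.20 Hz: cumulative reaches half at the
        # lower line under the >= convention
        n = 2000
        tt = np.arange(n) * TR
        x = np.sin(2 * np.pi * 0.05 * tt) + np.sin(2 * np.pi * 0.20 * tt)
        res = median_frequency(x, TR)
        assert abs(res.mf - 0.05) <= 2 / (n * TR)

    def test_flat_spectrum_converges_to_band_midpoint(self):
        # band-limited white noise: the equal-area point approaches the
        # midpoint of the band as the series grows
        n = 2**14
        mfs = []
        for seed in range(8):
            x = np.random.default_rng(seed).standard_normal(n)
            y = bandpass(x, dt=TR)
            mfs.append(median_frequency(y, TR).mf)
        assert np.mean(mfs) == pytest.approx(0.12, abs=0.005)

    def test_invariants(self, rng):
        y = bandpass(rng.standard_normal(4096), dt=TR)
        res = median_frequency(y, TR)
        lo, hi = res.band
        assert lo <= res.mf <= hi
        below = res.psd[res.freqs < res.mf].sum()
        at = res.psd[res.freqs <= res.mf].sum()
        assert below < 0.5 * res.psd.sum() <= at

    def test_errors(self):
        with pytest.raises(ValueError):
            median_frequency(np.zeros(4), TR)
        with pytest.raises(ValueError):
            median_frequency(np.ones(100), TR, band=(0.2299, 0.23))  # no bins
        with pytest.raises(ZeroVarianceError):
            median_frequency(np.ones(100), TR)


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        tt = np.arange(1000) * TR
        y = bandpass(np.sin(2 * np.pi * 0.10 * tt), dt=TR)
        assert np.ptp(y[100:-100]) / 2 >= 0.95

    def test_dc_removed(self):
        y = bandpass(np.full(500, 3.0) + 1e-6 * np.sin(np.arange(500)), dt=TR)
        assert abs(np.mean(y)) < 1e-3

    def test_out_of_band_attenuated(self):
        tt = np.arange(1000) * TR
        y = bandpass(np.sin(2 * np.pi * 0.002 * tt), dt=TR)
        assert np.abs(y).max() <= 0.1

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass(np.random.default_rng(0).standard_normal(20), dt=TR)

    def test_matrix_form_preserves_shape_and_meta(self, rng):
        ts = TimeSeriesMatrix(rng.standard_normal((145, 5)), dt=TR, meta={"state": "awake"})
        out = bandpass(ts)
        assert out.data.shape == (145, 5)
        assert out.meta["state"] == "awake"


class TestSlowDownMonotonicity:
    def test_lower_cutoff_never_shortens_acw_nor_raises_mf(self, rng):
        from scipy import signal as sig

        x = rng.standard_normal(4096)
        acws, mfs = [], []
        for cutoff in (0.20, 0.15, 0.10, 0.06, 0.03):
            sos = sig.butter(4, [0.01, cutoff], btype="bandpass", fs=1 / TR, output="sos")
            y = sig.sosfiltfilt(sos, x)
            acws.append(acf_with_acw(y, dt=TR).acw0)
            mfs.append(median_frequency(y, TR).mf)
        assert np.all(np.diff(acws) >= 0)
        assert np.all(np.diff(mfs) <= 0)


class TestMetricMap:
    def test_identical_columns_identical_values(self):
        x = np.sin(2 * np.pi * 0.05 * np.arange(145) * TR)
        ts = TimeSeriesMatrix(np.column_stack([x, x, x]), dt=TR)
        out = metric_map(ts, "acw0")
        assert out[0] == out[1] == out[2]

    def test_constant_column_gives_sentinel_not_abort(self, rng, caplog):
        data = np.column_stack(
            [rng.standard_normal(100), np.ones(100), rng.standard_normal(100)]
        )
        ts = TimeSeriesMatrix(data, dt=TR)
        with caplog.at_level(logging.WARNING):
            out = metric_map(ts, "acw0")
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()

    @pytest.mark.parametrize("metric", ["acw0", "acw50", "mf"])
    def test_matches_per_unit_loop(self, metric, rng):
        data = rng.standard_normal((145, 7))
        ts = TimeSeriesMatrix(data, dt=TR)
        got = metric_map(ts, metric)
        for j in range(7):
            if metric == "mf":
                expected = median_frequency(data[:, j], TR).mf
            else:
                res = acf_with_acw(data[:, j], dt=TR)
                expected = getattr(res, metric)
            assert got[j] == pytest.approx(expected, nan_ok=True)

    def test_thousand_parcel_sweep_shape(self, rng):
        ts = TimeSeriesMatrix(rng.standard_normal((145, 1000)), dt=TR)
        assert metric_map(ts, "mf").shape == (1000,)


class TestTimeSeriesMatrix:
    def test_invariants_enforced(self, rng):
        with pytest.raises(ValueError):
            TimeSeriesMatrix(rng.standard_normal((2, 3)), dt=TR)
        with pytest.raises(ValueError):
            TimeSeriesMatrix(rng.standard_normal((10, 2)), dt=0.0)
        with pytest.raises(ValueError):
            TimeSeriesMatrix(rng.standard_normal((10, 2)), dt=TR, unit_ids=["a", "a"])
        bad = rng.standard_normal((10, 2))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError):
            TimeSeriesMatrix(bad, dt=TR)
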