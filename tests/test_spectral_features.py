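"""Welch PSD estimator, sub-band extraction, and the band scan."""

import numpy as np
import pytest
from scipy.signal import welch as scipy_welch

from mitopo.classifiers import BandPowerLogistic
from mitopo.spectral_features import (
    BandScanResult,
    PSDEstimate,
    WelchConfig,
    band_scan,
    subband_power,
    welch_psd,
)
from mitopo.synthetic_data import SyntheticConfig, generate

FS = 160.0


def brute_force_periodogram(x, window, fs):
    """Direct evaluation of the windowed periodogram, no library PSD.

    One-sided density: |sum_n x(n) w(n) e^{-j w n}|^2 / (U M fs), with
    U = (1/M) sum w^2 and a factor 2 on interior bins.
    """
    m = len(x)
    u = np.sum(window**2) / m
    n_bins = m // 2 + 1
    out = np.empty(n_bins)
    n = np.arange(m)
    for k in range(n_bins):
        s = np.sum(x * window * np.exp(-2j * np.pi * k * n / m))
        out[k] = np.abs(s) ** 2 / (u * m * fs)
        if 0 < k < (m + 1) // 2 or (m % 2 == 0 and 0 < k < m // 2):
            out[k] *= 2
        elif m % 2 == 0 and k == m // 2:
            pass  # Nyquist bin not doubled
    return out


class TestWelch:
    def test_zero_signal_zero_psd(self):
        psd = welch_psd(np.zeros(640), FS)
        assert np.all(psd.power == 0)

    def test_two_contiguous_blocks_average(self):
        # N=640, M=320 -> exactly blocks [0,320) and [320,640)
        rng = np.random.default_rng(5)
        x = rng.normal(size=640)
        cfg = WelchConfig(segment_length=320)
        full = welch_psd(x, FS, cfg)
        one = WelchConfig(segment_length=320, n_segments=1)
        first = welch_psd(x[:320], FS, one)
        second = welch_psd(x[320:], FS, one)
        np.testing.assert_array_equal(
            full.power, (first.power + second.power) / 2.0
        )

    def test_matches_brute_force_oracle_rectangular(self):
        # unit sinusoid at an exact bin, rectangular window, single block
        m = 64
        k0 = 10
        t = np.arange(m)
        x = np.sin(2 * np.pi * k0 * t / m)
        cfg = WelchConfig(segment_length=m, n_segments=1, window="rectangular")
        psd = welch_psd(x, FS, cfg)
        oracle = brute_force_periodogram(x, np.ones(m), FS)
        assert np.max(np.abs(psd.power[0] - oracle)) < 1e-10

    def test_matches_brute_force_oracle_hamming(self, rng):
        m = 48
        x = rng.normal(size=m)
        cfg = WelchConfig(segment_length=m, n_segments=1, window="hamming")
        psd = welch_psd(x, FS, cfg)
        oracle = brute_force_periodogram(x, cfg.taper(), FS)
        assert np.max(np.abs(psd.power[0] - oracle)) < 1e-10

    def test_agrees_with_scipy(self, rng):
        x = rng.normal(size=(3, 640))
        cfg = WelchConfig(segment_length=320)
        ours = welch_psd(x, FS, cfg)
        f_sp, p_sp = scipy_welch(
            x, fs=FS, window="hamming", nperseg=320, noverlap=0, detrend=False
        )
        np.testing.assert_allclose(ours.frequencies, f_sp)
        np.testing.assert_allclose(ours.power, p_sp, rtol=1e-10)

    def test_parseval_white_noise(self, rng):
        x = rng.normal(size=640)
        cfg = WelchConfig(segment_length=320, window="rectangular")
        psd = welch_psd(x, FS, cfg)
        recovered = psd.power.sum() * psd.resolution
        assert abs(recovered - x.var()) / x.var() < 0.05

    def test_averaging_reduces_variance(self):
        rng = np.random.default_rng(7)
        var1, var4 = [], []
        for _ in range(200):
            x = rng.normal(size=640)
            p1 = welch_psd(x, FS, WelchConfig(segment_length=640)).power
            p4 = welch_psd(x, FS, WelchConfig(segment_length=160)).power
            var1.append(p1[0, 10:300].var())
            var4.append(p4[0, 5:75].var())
        assert np.mean(var4) < np.mean(var1)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), FS, WelchConfig(segment_length=320))
        with pytest.raises(ValueError):
            welch_psd(np.zeros(640), FS, WelchConfig(segment_length=320, n_segments=3))


class TestSubbands:
    def _flat_psd(self, value=1.0):
        freqs = np.fft.rfftfreq(320, 1 / FS)
        return PSDEstimate(freqs, np.full((1, freqs.size), value))

    def test_default_edges(self):
        sb = subband_power(self._flat_psd(), (10.0, 15.0), 10)
        lows = [e[0] for e in sb.band_edges]
        np.testing.assert_allclose(lows, 10.0 + 0.5 * np.arange(10))
        assert sb.band_edges[-1] == (14.5, 15.0)

    def test_flat_psd_gives_constant(self):
        sb = subband_power(self._flat_psd(3.14), (10.0, 15.0), 10)
        np.testing.assert_allclose(sb.power, 3.14)

    def test_single_bin_membership(self):
        # power only at 10.0 Hz (bin 20 at 0.5 Hz resolution): the first
        # sub-band [10, 10.5) holds it, all others are zero
        freqs = np.fft.rfftfreq(320, 1 / FS)
        power = np.zeros((1, freqs.size))
        power[0, np.argmin(np.abs(freqs - 10.0))] = 7.0
        sb = subband_power(PSDEstimate(freqs, power), (10.0, 15.0), 10)
        np.testing.assert_allclose(sb.power[0], [7.0] + [0.0] * 9)

    def test_resolution_limit_reported(self):
        freqs = np.fft.rfftfreq(64, 1 / FS)  # 2.5 Hz resolution
        psd = PSDEstimate(freqs, np.ones((1, freqs.size)))
        with pytest.raises(ValueError, match="segment_length"):
            subband_power(psd, (10.0, 15.0), 10)


class _ConstantClassifier:
    """Predicts the first label seen: same accuracy for every band."""

    def fit(self, tensors, labels):
        self._label = labels[0]
        return self

    def predict(self, tensors):
        return np.repeat(self._label, len(tensors))


class TestBandScan:
    def test_six_five_hz_bands(self, erd_segments):
        result = band_scan(
            erd_segments, 5.0, 35.0, 5.0, eval_fn=_ConstantClassifier, n_splits=1
        )
        assert result.bands == [
            (5.0, 10.0), (10.0, 15.0), (15.0, 20.0),
            (20.0, 25.0), (25.0, 30.0), (30.0, 35.0),
        ]

    def test_tie_breaks_to_lowest_band(self, erd_segments):
        result = band_scan(
            erd_segments, 5.0, 35.0, 5.0, eval_fn=_ConstantClassifier, n_splits=1
        )
        assert np.ptp(result.mean_accuracy) == 0
        assert result.selected_band == (5.0, 10.0)

    def test_selects_mu_band_on_erd_data(self):
        segs = generate(
            SyntheticConfig(n_trials_per_class=50, erd_effect=0.6, seed=21)
        )
        result = band_scan(segs, 5.0, 35.0, 5.0, eval_fn=BandPowerLogistic)
        assert result.selected_band == (10.0, 15.0)

    def test_range_not_divisible_rejected(self, erd_segments):
        with pytest.raises(ValueError):
            band_scan(erd_segments, 5.0, 33.0, 5.0, eval_fn=_ConstantClassifier)

    def test_single_class_rejected(self, erd_segments):
        left_only = [s for s in erd_segments if s.class_label == "left_fist"]
        with pytest.raises(ValueError):
            band_scan(left_only, 5.0, 35.0, 5.0, eval_fn=_ConstantClassifier)
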