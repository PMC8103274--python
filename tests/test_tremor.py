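"""Spectral pipeline: preprocessing, Welch PSD, and tremor-peak extraction."""

import math

import numpy as np
import pytest

from vrmotor import (
    KinematicTrace,
    TraceError,
    extract_tremor_features,
    preprocess_trace,
    simulate_tremor_trace,
    trace_features,
    welch_psd,
)
from vrmotor.errors import AnalysisError


def dft_periodogram(x, fs):
    """Brute-force one-sided DFT periodogram (density scaling)."""
    n = len(x)
    k = np.arange(n)
    dft = np.array(
        [np.sum(x * np.exp(-2j * np.pi * kk * k / n)) for kk in range(n // 2 + 1)]
    )
    psd = np.abs(dft) ** 2 / (fs * n)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    return np.arange(n // 2 + 1) * fs / n, psd


def uniform_trace(duration=10.0, rate=90.0, signal=None):
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    pos = np.zeros((n, 3))
    if signal is not None:
        pos[:, 0] = signal(t)
    return KinematicTrace(hand="right", condition="posture", trial_index=2, t=t, pos=pos)


class TestPreprocess:
    def test_ten_second_trace_trims_to_630_samples(self):
        sig, rate = preprocess_trace(uniform_trace())
        assert sig.shape == (630, 3)
        assert rate == 90.0

    def test_uniform_trace_resampling_is_identity(self):
        trace = uniform_trace(signal=lambda t: np.sin(2 * np.pi * 4 * t))
        sig, _ = preprocess_trace(trace, trim_s=3.0)
        from scipy.signal import detrend

        expected = detrend(trace.pos[270:, 0], type="linear")
        assert np.allclose(sig[:, 0], expected, atol=1e-12)

    def test_jittered_ramp_detrends_to_zero(self):
        rng = np.random.default_rng(0)
        n = 900
        t = np.arange(n) / 90.0 + rng.uniform(-1e-3, 1e-3, n)
        t = np.sort(t)
        pos = np.zeros((n, 3))
        pos[:, 1] = 0.3 + 1.7 * t  # pure linear ramp
        trace = KinematicTrace("left", "rest", 2, t, pos)
        sig, _ = preprocess_trace(trace)
        assert np.max(np.abs(sig)) < 1e-9

    def test_too_short_trace_raises(self):
        with pytest.raises(TraceError):
            preprocess_trace(uniform_trace(duration=2.5), trim_s=3.0)

    @pytest.mark.parametrize(
        "mutator",
        [
            lambda t, pos, q: (t[::-1].copy(), pos, q),  # decreasing timestamps
            lambda t, pos, q: (t, pos, q * 1.01),  # non-unit quaternions
            lambda t, pos, q: (t * 5.0, pos, q),  # wrong nominal rate
        ],
    )
    def test_invalid_traces_rejected(self, mutator):
        n = 900
        t = np.arange(n) / 90.0
        pos = np.zeros((n, 3))
        q = np.zeros((n, 4))
        q[:, 0] = 1.0
        t2, p2, q2 = mutator(t, pos, q)
        with pytest.raises(TraceError):
            KinematicTrace("left", "rest", 1, t2, p2, q2)


class TestWelch:
    def test_zero_signal_gives_zero_psd(self):
        freqs, psd = welch_psd(np.zeros(900), 90.0)
        assert np.all(psd == 0)

    def test_single_segment_rectangular_equals_dft_periodogram(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=256)
        freqs, psd = welch_psd(
            x, 90.0, segment_len=256, overlap=0.0, window="boxcar", detrend=False
        )
        f_ref, p_ref = dft_periodogram(x, 90.0)
        assert np.allclose(freqs, f_ref)
        nz = p_ref > 0
        assert np.max(np.abs(psd[nz] - p_ref[nz]) / p_ref[nz]) < 1e-10

    def test_psd_integral_matches_variance_for_white_noise(self):
        sigma = 0.3
        integrals = []
        for seed in range(50):
            x = np.random.default_rng(seed).normal(0, sigma, 2048)
            freqs, psd = welch_psd(x, 90.0, segment_len=256, detrend=False)
            integrals.append(np.trapezoid(psd, freqs))
        assert abs(np.mean(integrals) - sigma**2) / sigma**2 < 0.10

    def test_segment_longer_than_signal_raises(self):
        with pytest.raises(AnalysisError):
            welch_psd(np.zeros(100), 90.0, segment_len=256)


class TestFeatureExtraction:
    def test_sinusoid_frequency_recovered_within_one_bin(self):
        trace = simulate_tremor_trace(
            amp=0.01, freq=4.7, duration=10, rate=90, noise_sd=1e-4, seed=5
        )
        feats = trace_features(trace)
        bin_width = 90.0 / 256
        assert abs(feats.dominant_frequency - 4.7) <= bin_width

    def test_peak_power_quadratic_in_amplitude(self):
        def peak(amp):
            trace = simulate_tremor_trace(
                amp=amp, freq=5.0, duration=10, rate=90, noise_sd=0.0, seed=1
            )
            return trace_features(trace).peak_power

        assert abs(peak(0.02) / peak(0.01) - 4.0) < 0.2  # x2 amplitude -> x4 power

    def test_zero_signal_yields_no_peak_sentinel(self):
        feats = trace_features(uniform_trace())
        assert feats.peak_power == 0.0
        assert math.isnan(feats.dominant_frequency)
        assert not feats.has_peak

    def test_transient_confined_to_trim_window_is_invisible(self):
        def clean(t):
            return 0.005 * np.sin(2 * np.pi * 5 * t)

        def with_transient(t):
            return clean(t) + np.where(t < 2.9, 0.05 * np.sin(2 * np.pi * 9 * t), 0.0)

        f1 = trace_features(uniform_trace(signal=clean))
        f2 = trace_features(uniform_trace(signal=with_transient))
        assert f1.peak_power == f2.peak_power
        assert f1.dominant_frequency == f2.dominant_frequency

    def test_empty_band_rejected(self):
        freqs = np.linspace(0, 45, 129)
        psd = np.ones((3, 129))
        with pytest.raises(AnalysisError):
            extract_tremor_features(freqs, psd, band=(8.0, 8.0))

    def test_axis_maximum_is_reported(self):
        freqs = np.linspace(0, 45, 129)
        psd = np.zeros((3, 129))
        psd[1, 20] = 5.0  # strongest on axis y
        psd[0, 30] = 2.0
        feats = extract_tremor_features(freqs, psd)
        assert feats.peak_power == 5.0
        assert feats.dominant_frequency == pytest.approx(freqs[20])


@pytest.mark.parametrize("f0", np.arange(1.0, 12.1, 0.5))
def test_frequency_grid_recovery(f0):
    """Injected tremor across the whole band is recovered at high SNR."""
    trace = simulate_tremor_trace(
        amp=0.01, freq=float(f0), duration=10, rate=90, noise_sd=5e-4, seed=int(f0 * 10)
    )
    feats = trace_features(trace)
    assert abs(feats.dominant_frequency - f0) <= 90.0 / 256
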