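"""Envelope tracer: STFT front end, percentile tracing, velocity conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopplervti import DopplerConfig, ParameterError, VelocityEnvelope
from dopplervti.envelope import (
    Spectrogram,
    compute_spectrogram,
    frequency_to_velocity,
    trace_envelope,
    trace_max_frequency,
    velocity_to_frequency,
)
from dopplervti.errors import InputFormatError
from dopplervti.sim import synthesize_channel_audio


def brute_force_percentile_frequency(power, bins, percentile):
    """Independent oracle: piecewise-linear cumulative crossing, zero floor."""
    cum = np.cumsum(power)
    target = percentile * cum[-1]
    i = int(np.argmax(cum >= target))
    if i == 0:
        return bins[0]
    frac = (target - cum[i - 1]) / (cum[i] - cum[i - 1])
    return bins[i - 1] + frac * (bins[i] - bins[i - 1])


class TestSpectrogram:
    def test_frame_count_formula(self):
        # 44100 samples, 441-sample window, 110-sample hop
        audio = np.zeros(44100)
        spec = compute_spectrogram(audio, 44100.0, 0.010, 0.0025)
        assert spec.frame_times.size == (44100 - 441) // 110 + 1 == 397

    def test_pure_tone_peaks_at_tone_bin(self):
        fs = 44100.0
        t = np.arange(int(fs)) / fs
        audio = np.sin(2 * np.pi * 5000.0 * t)
        spec = compute_spectrogram(audio, fs)
        mean_power = spec.power.mean(axis=0)
        peak_freq = spec.frequency_bins[np.argmax(mean_power)]
        assert abs(peak_freq - 5000.0) <= fs / 441  # within one bin

    def test_all_zero_audio_gives_zero_power(self):
        spec = compute_spectrogram(np.zeros(4410), 44100.0)
        assert np.all(spec.power == 0)

    def test_audio_shorter_than_window_rejected(self):
        with pytest.raises(InputFormatError):
            compute_spectrogram(np.zeros(100), 44100.0, 0.010, 0.0025)


class TestTraceMaxFrequency:
    def _uniform_spec(self, n_frames=7, n_bins=221, hi_bin=51, df=100.0):
        power = np.zeros((n_frames, n_bins))
        power[:, :hi_bin] = 1.0
        return Spectrogram(
            np.arange(n_frames) * 0.0025, np.arange(n_bins) * df, power, 0.01, 0.0025
        )

    def test_uniform_spectrum_matches_cumulative_oracle(self):
        spec = self._uniform_spec()
        freqs, quality = trace_max_frequency(spec, smooth_frames=1)
        expected = brute_force_percentile_frequency(spec.power[0], spec.frequency_bins, 0.95)
        assert quality.all()
        # 95% of a uniform 0..5000 Hz spectrum sits near 4750 Hz
        assert abs(expected - 4750.0) <= 100.0
        assert freqs[3] == pytest.approx(expected, abs=1e-9)

    def test_raising_percentile_never_lowers_the_trace(self):
        rng = np.random.default_rng(7)
        power = rng.random((20, 100))
        spec = Spectrogram(np.arange(20) * 0.0025, np.arange(100) * 50.0, power, 0.01, 0.0025)
        prev = None
        for p in (0.5, 0.7, 0.9, 0.95, 0.99):
            freqs, _ = trace_max_frequency(spec, percentile=p, smooth_frames=1)
            if prev is not None:
                assert np.all(freqs >= prev - 1e-9)
            prev = freqs

    def test_flat_noise_frame_is_masked(self):
        power = np.full((9, 64), 3.14)
        spec = Spectrogram(np.arange(9) * 0.0025, np.arange(64) * 100.0, power, 0.01, 0.0025)
        freqs, quality = trace_max_frequency(spec)
        assert not quality.any()
        assert np.all(freqs == 0.0)

    def test_invalid_parameters_rejected(self):
        spec = self._uniform_spec()
        with pytest.raises(ParameterError):
            trace_max_frequency(spec, percentile=1.5)
        with pytest.raises(ParameterError):
            trace_max_frequency(spec, smooth_frames=4)


class TestVelocityConversion:
    def test_known_shift_maps_to_100_cm_s(self, doppler_config):
        v = frequency_to_velocity(2 * 4e6 * 1.0 / 1540.0, doppler_config)
        assert v == pytest.approx(100.0, rel=1e-12)
        assert frequency_to_velocity(0.0, doppler_config) == 0.0

    def test_60_degree_angle_doubles_velocity(self):
        straight = DopplerConfig()
        angled = DopplerConfig(insonation_angle_deg=60.0)
        assert frequency_to_velocity(1000.0, angled) == pytest.approx(
            2.0 * frequency_to_velocity(1000.0, straight), rel=1e-9
        )

    def test_perpendicular_beam_rejected(self):
        with pytest.raises(ParameterError):
            DopplerConfig(insonation_angle_deg=90.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=20000.0, allow_nan=False))
    def test_round_trip_is_exact(self, f):
        cfg = DopplerConfig(insonation_angle_deg=30.0)
        assert velocity_to_frequency(frequency_to_velocity(f, cfg), cfg) == pytest.approx(
            f, rel=1e-12, abs=1e-9
        )


class TestEnvelopeRecovery:
    def test_single_tone_traced_within_one_bin(self, doppler_config):
        env = VelocityEnvelope(np.arange(0, 2, 1 / 400), np.full(800, 100.0))
        audio = synthesize_channel_audio(env, doppler_config, snr_db=np.inf, seed=0, n_scatterers=1)
        traced = trace_envelope(audio.astype(float), 44100.0, doppler_config)
        bin_equiv = frequency_to_velocity(44100.0 / 441, doppler_config)
        good = traced.quality
        assert good.mean() > 0.95
        assert np.all(np.abs(traced.velocity_cm_s[good] - 100.0) <= bin_equiv)

    def test_scatterer_audio_at_snr_30_within_5_percent(self, doppler_config):
        # full scatterer model on a slow modulated envelope in the systolic
        # carotid range, where one frequency bin is well under 5% of the shift
        t = np.arange(0, 10, 1 / 400)
        v = 100 + 20 * np.sin(2 * np.pi * 0.5 * t)
        env = VelocityEnvelope(t, v)
        audio = synthesize_channel_audio(env, doppler_config, snr_db=30.0, seed=2)
        traced = trace_envelope(audio.astype(float), 44100.0, doppler_config)
        vt = np.interp(traced.frame_times, t, v)
        good = traced.quality
        rel_err = np.abs(traced.velocity_cm_s[good] - vt[good]) / vt[good]
        assert np.mean(rel_err <= 0.05) >= 0.95
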