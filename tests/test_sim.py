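"""Simulator: beat morphology, programmed trajectories, audio synthesis."""

import numpy as np
import pytest

from dopplervti import (
    BeatShapeParams,
    ConfigurationError,
    DopplerConfig,
    ParameterError,
    ValsalvaProfile,
    VelocityEnvelope,
)
from dopplervti.beats import compute_beat_vti
from dopplervti.protocol import beat_window_mean, percent_change
from dopplervti.sim import (
    default_shapes,
    make_beat_onsets,
    make_beat_waveform,
    make_velocity_track,
    paper_cohort_profiles,
    simulate_cohort,
    simulate_sv_channel,
    synthesize_channel_audio,
)

T1, T2 = (5.0, 10.0), (25.0, 30.0)


class TestBeatWaveform:
    @pytest.mark.parametrize("edv", [0.0, 20.0])
    def test_bounds_and_endpoints(self, edv):
        shape = BeatShapeParams(
            peak_systolic_velocity_cm_s=100.0, end_diastolic_velocity_cm_s=edv
        )
        t, v = make_beat_waveform(shape, 0.5, 400.0)
        assert v[0] == pytest.approx(edv, abs=1e-9)
        assert v[-1] == pytest.approx(edv, abs=1e-6)
        assert np.max(v) == pytest.approx(100.0, rel=1e-6)
        assert np.min(v) >= -1e-9
        # peak sits at the end of the systolic rise
        assert t[np.argmax(v)] == pytest.approx(
            shape.systolic_rise_fraction * 0.5, abs=2.5 / 400.0
        )

    def test_half_sine_area_matches_closed_form(self, half_sine_shape):
        # analytic area of v(t) = 100 sin(pi t / 0.5): 2 * 100 * 0.5 / pi
        t, v = make_beat_waveform(half_sine_shape, 0.5, 400.0)
        area = np.trapezoid(v, t)
        assert area == pytest.approx(2.0 * 100.0 * 0.5 / np.pi, rel=1e-4)

    def test_dicrotic_notch_creates_secondary_minimum(self):
        shape = BeatShapeParams(dicrotic_notch_depth=0.4)
        _, v = make_beat_waveform(shape, 0.8, 400.0)
        interior = v[5:-5]
        minima = np.flatnonzero(
            (interior[1:-1] < interior[:-2]) & (interior[1:-1] < interior[2:])
        )
        assert minima.size >= 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"peak_systolic_velocity_cm_s": -1.0},
            {"end_diastolic_velocity_cm_s": 120.0},
            {"systolic_rise_fraction": 0.7},
            {"dicrotic_notch_depth": 1.5},
            {"peak_systolic_velocity_cm_s": float("nan")},
        ],
    )
    def test_invalid_shape_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            BeatShapeParams(**kwargs)

    def test_too_few_samples_rejected(self, half_sine_shape):
        with pytest.raises(ParameterError):
            make_beat_waveform(half_sine_shape, 0.5, 10.0)


class TestVelocityTrack:
    def test_identity_profile_gives_equal_beats(self):
        profile = ValsalvaProfile()
        truth = make_velocity_track(profile, default_shapes()["carotid"], seed=0)
        # equal up to frame-grid discretisation of beat boundaries (~hop x edv)
        assert np.allclose(truth.true_beat_vti, truth.true_beat_vti[0], rtol=2e-3)
        a = beat_window_mean(truth.true_beat_onsets, truth.true_beat_vti, T1)
        b = beat_window_mean(truth.true_beat_onsets, truth.true_beat_vti, T2)
        assert percent_change(a, b) == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize(
        "channel,expected_pct", [("carotid", -23.0), ("aortic", -37.0)]
    )
    def test_paper_cohort_programmed_fall(self, calibrated_tracks, channel, expected_pct):
        truth = calibrated_tracks[channel]
        a = beat_window_mean(truth.true_beat_onsets, truth.true_beat_vti, T1)
        b = beat_window_mean(truth.true_beat_onsets, truth.true_beat_vti, T2)
        assert percent_change(a, b) == pytest.approx(expected_pct, abs=0.1)

    def test_self_consistency_of_beat_vti(self, calibrated_tracks):
        truth = calibrated_tracks["carotid"]
        bounds = np.append(
            truth.true_beat_onsets,
            truth.true_beat_onsets[-1] + truth.true_beat_durations[-1],
        )
        recomputed = compute_beat_vti(truth.true_envelope, bounds)
        assert np.max(np.abs(recomputed - truth.true_beat_vti) / truth.true_beat_vti) < 1e-3

    def test_hold_heart_rate_scaling(self, calibrated_tracks):
        truth = calibrated_tracks["carotid"]
        hr = 60.0 / truth.true_beat_durations
        hold_hr = beat_window_mean(truth.true_beat_onsets, hr, T2)
        assert hold_hr == pytest.approx(72.0 * 1.21, rel=1e-3)

    def test_low_frame_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            make_velocity_track(ValsalvaProfile(), default_shapes()["carotid"], frame_rate_hz=5.0)


class TestSvChannel:
    def test_paper_cohort_sv_and_map_changes(self):
        profile = paper_cohort_profiles(jitter=False)["carotid"]
        sv = simulate_sv_channel(profile)
        assert sv.sample_times_s[0] == 0.0
        i_min = int(np.argmin(sv.sv_ml[1:]) + 1)
        assert percent_change(sv.sv_ml[0], sv.sv_ml[i_min]) == pytest.approx(-26.0, abs=0.1)
        assert percent_change(sv.map_mmhg[0], sv.map_mmhg[i_min]) == pytest.approx(4.0, abs=0.1)

    def test_identity_profile_constant(self):
        sv = simulate_sv_channel(ValsalvaProfile())
        assert np.allclose(sv.sv_ml, sv.sv_ml[0])
        assert np.allclose(sv.map_mmhg, sv.map_mmhg[0])


class TestAudioSynthesis:
    def test_constant_velocity_spectral_edge(self, doppler_config):
        env = VelocityEnvelope(np.arange(0, 2, 1 / 400), np.full(800, 100.0))
        audio = synthesize_channel_audio(env, doppler_config, snr_db=np.inf, seed=0)
        spec = np.abs(np.fft.rfft(audio.astype(float))) ** 2
        freqs = np.fft.rfftfreq(audio.size, 1 / doppler_config.audio_sample_rate_hz)
        cum = np.cumsum(spec) / spec.sum()
        edge = 2 * 4e6 * 1.0 / 1540.0  # 100 cm/s at 4 MHz: about 5195 Hz
        f99 = freqs[np.argmax(cum >= 0.99)]
        assert 0.90 * edge <= f99 <= 1.05 * edge

    def test_zero_envelope_noiseless_is_silence(self, doppler_config):
        env = VelocityEnvelope(np.arange(0, 1, 1 / 400), np.zeros(400))
        audio = synthesize_channel_audio(env, doppler_config, snr_db=np.inf, seed=1)
        assert np.all(audio == 0)

    def test_determinism_is_bitwise(self, doppler_config):
        env = VelocityEnvelope(np.arange(0, 2, 1 / 400), np.full(800, 80.0))
        a = synthesize_channel_audio(env, doppler_config, snr_db=20.0, seed=5)
        b = synthesize_channel_audio(env, doppler_config, snr_db=20.0, seed=5)
        assert np.array_equal(a, b)

    def test_nyquist_violation_rejected(self):
        cfg = DopplerConfig(audio_sample_rate_hz=8000.0)
        env = VelocityEnvelope(np.arange(0, 1, 1 / 400), np.full(400, 100.0))
        with pytest.raises(ConfigurationError):
            synthesize_channel_audio(env, cfg, seed=0)


class TestCohort:
    def test_responders_and_controls_by_construction(self):
        responders = simulate_cohort(4, 0, seed=11, render_audio=False)
        windows = (T1, T2)
        for s in responders:
            truth = s.aortic_truth
            a = beat_window_mean(truth.true_beat_onsets, truth.true_beat_vti, windows[0])
            b = beat_window_mean(truth.true_beat_onsets, truth.true_beat_vti, windows[1])
            assert percent_change(a, b) < -10.0
        controls = simulate_cohort(0, 4, seed=11, render_audio=False)
        for s in controls:
            truth = s.aortic_truth
            a = beat_window_mean(truth.true_beat_onsets, truth.true_beat_vti, windows[0])
            b = beat_window_mean(truth.true_beat_onsets, truth.true_beat_vti, windows[1])
            assert abs(percent_change(a, b)) < 10.0

    def test_cohort_ground_truth_reproducible(self):
        a = simulate_cohort(2, 2, seed=42, render_audio=False)
        b = simulate_cohort(2, 2, seed=42, render_audio=False)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(
                sa.carotid_truth.true_envelope.velocity_cm_s,
                sb.carotid_truth.true_envelope.velocity_cm_s,
            )
            assert np.array_equal(sa.sv_series.sv_ml, sb.sv_series.sv_ml)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            simulate_cohort(0, 0, seed=1)
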