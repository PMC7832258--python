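"""Beat segmentation, per-beat VTI and heart rate."""

import numpy as np
import pytest

from dopplervti import InputFormatError, InsufficientSignalError, VelocityEnvelope
from dopplervti.beats import build_beat_table, compute_beat_vti, compute_hr, detect_beats
from dopplervti.envelope import trace_envelope

from conftest import periodic_envelope


class TestDetectBeats:
    def test_periodic_envelope_at_60_bpm(self):
        env = periodic_envelope(n_beats=10, beat_duration_s=1.0)
        onsets = detect_beats(env)
        assert onsets.size == 10
        assert np.allclose(np.diff(onsets), 1.0, atol=0.01)

    def test_flat_envelope_raises(self):
        env = VelocityEnvelope(np.arange(0, 5, 1 / 400), np.zeros(2000))
        with pytest.raises(InsufficientSignalError):
            detect_beats(env)

    def test_too_short_envelope_raises(self):
        env = periodic_envelope(n_beats=1, beat_duration_s=1.0)
        with pytest.raises(InsufficientSignalError):
            detect_beats(env)


class TestComputeBeatVti:
    def test_half_sine_matches_closed_form(self, half_sine_shape):
        from dopplervti.sim import _unit_waveform

        t = np.arange(0, 1.0, 1 / 400)
        v = np.where(t < 0.5, _unit_waveform(half_sine_shape, np.minimum(t / 0.5, 1.0)), 0.0)
        env = VelocityEnvelope(t, v)
        vti = compute_beat_vti(env, np.array([0.0, 0.5]))
        assert vti[0] == pytest.approx(2 * 100 * 0.5 / np.pi, rel=0.01)

    def test_constant_envelope_rectangle(self):
        env = VelocityEnvelope(np.arange(0, 2, 1 / 400), np.full(800, 50.0))
        vti = compute_beat_vti(env, np.array([0.0, 1.0]))
        assert vti[0] == pytest.approx(50.0, rel=1e-6)

    def test_linearity_in_amplitude(self):
        env = periodic_envelope(n_beats=4)
        doubled = VelocityEnvelope(env.frame_times, 2 * env.velocity_cm_s)
        onsets = np.array([0.0, 1.0, 2.0, 3.0])
        assert np.allclose(
            compute_beat_vti(doubled, onsets), 2 * compute_beat_vti(env, onsets), rtol=1e-12
        )

    def test_conservation_over_contiguous_beats(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 8, 1 / 400)
        v = 50 + 20 * np.sin(2 * np.pi * 1.1 * t) + rng.normal(0, 1, t.size).cumsum() * 0.01
        v = np.abs(v)
        env = VelocityEnvelope(t, v)
        onsets = np.array([0.5, 1.4, 2.2, 3.3, 4.1, 5.0, 6.2, 7.5])
        vtis = compute_beat_vti(env, onsets)
        idx = np.searchsorted(t, [onsets[0], onsets[-1]], side="left")
        total = np.trapezoid(v[idx[0] : idx[1] + 1], t[idx[0] : idx[1] + 1])
        assert vtis.sum() == pytest.approx(total, rel=1e-12)

    def test_bad_onsets_rejected(self):
        env = periodic_envelope(n_beats=4)
        with pytest.raises(InputFormatError):
            compute_beat_vti(env, np.array([1.0]))
        with pytest.raises(InputFormatError):
            compute_beat_vti(env, np.array([2.0, 1.0]))


class TestComputeHr:
    def test_uniform_onsets(self):
        assert np.allclose(compute_hr(np.array([0.0, 1.0, 2.0])), [60.0, 60.0])
        assert compute_hr(np.array([0.0, 0.5]))[0] == pytest.approx(120.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(InputFormatError):
            compute_hr(np.array([0.0, 2.0, 1.0]))


@pytest.fixture(scope="module")
def traced_subject():
    from dopplervti.sim import simulate_subject

    subject = simulate_subject("s", True, seed=9, snr_db=20.0)
    env = trace_envelope(
        subject.audio[:, 0].astype(float), subject.sample_rate_hz, subject.config
    )
    return subject, build_beat_table(env)


class TestAgainstSimulatorTruth:
    def test_onsets_match_truth_within_50_ms(self, traced_subject):
        subject, table = traced_subject
        true_onsets = subject.carotid_truth.true_beat_onsets[:-1]
        nearest = np.array(
            [np.min(np.abs(table.onset_times_s - t)) for t in true_onsets]
        )
        assert np.mean(nearest <= 0.05) >= 0.95

    def test_vti_within_5_percent_of_truth(self, traced_subject):
        subject, table = traced_subject
        truth = subject.carotid_truth
        errs = []
        for i, t in enumerate(truth.true_beat_onsets[:-1]):
            j = int(np.argmin(np.abs(table.onset_times_s - t)))
            if abs(table.onset_times_s[j] - t) <= 0.05 and table.kept[j]:
                errs.append(
                    abs(table.vti_cm[j] - truth.true_beat_vti[i]) / truth.true_beat_vti[i]
                )
        assert len(errs) >= 0.9 * (truth.true_beat_onsets.size - 1)
        assert np.percentile(errs, 95) < 0.05

    def test_hold_hr_recovered(self, traced_subject):
        subject, table = traced_subject
        mask = (table.onset_times_s >= 25) & (table.onset_times_s < 30)
        profile = subject.carotid_truth.profile
        expected = profile.baseline_hr_bpm * profile.hold_hr_multiplier
        assert np.mean(table.hr_bpm[mask]) == pytest.approx(expected, rel=0.05)


class TestQualityMask:
    def test_beats_over_masked_frames_are_dropped(self):
        env = periodic_envelope(n_beats=6)
        quality = np.ones(env.frame_times.size, dtype=bool)
        quality[(env.frame_times >= 2.2) & (env.frame_times <= 2.4)] = False
        masked_env = VelocityEnvelope(env.frame_times, env.velocity_cm_s, quality)
        table = build_beat_table(masked_env)
        overlapping = (table.onset_times_s < 2.4) & (table.onset_times_s + table.rr_s > 2.2)
        assert not table.kept[overlapping].any()
        assert table.kept[~overlapping].all()
        assert len(table.dropped) == int(overlapping.sum())
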