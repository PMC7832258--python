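import numpy as np
import pytest

from dopplervti import (
    BeatShapeParams,
    DopplerConfig,
    ValsalvaProfile,
    VelocityEnvelope,
)
from dopplervti.sim import default_shapes, make_beat_onsets, make_velocity_track, paper_cohort_profiles


@pytest.fixture
def doppler_config() -> DopplerConfig:
    return DopplerConfig()


@pytest.fixture
def half_sine_shape() -> BeatShapeParams:
    return BeatShapeParams(
        peak_systolic_velocity_cm_s=100.0,
        end_diastolic_velocity_cm_s=0.0,
        dicrotic_notch_depth=0.0,
        half_sine=True,
    )


@pytest.fixture
def calibrated_tracks():
    """Zero-jitter, phase-locked carotid + aortic ground truth for one subject."""
    profiles = paper_cohort_profiles(jitter=False)
    shapes = default_shapes()
    onsets, durations = make_beat_onsets(profiles["carotid"], 0)
    carotid = make_velocity_track(
        profiles["carotid"], shapes["carotid"], onsets=onsets, durations=durations
    )
    aortic = make_velocity_track(
        profiles["aortic"], shapes["aortic"], onsets=onsets, durations=durations
    )
    return {"carotid": carotid, "aortic": aortic, "profiles": profiles}


def periodic_envelope(
    n_beats: int = 10,
    beat_duration_s: float = 1.0,
    frame_rate_hz: float = 400.0,
    peak: float = 100.0,
    edv: float = 10.0,
) -> VelocityEnvelope:
    """Noise-free strictly periodic envelope used by beat-segmentation tests."""
    shape = BeatShapeParams(
        peak_systolic_velocity_cm_s=peak, end_diastolic_velocity_cm_s=edv
    )
    from dopplervti.sim import _unit_waveform

    t = np.arange(0.0, n_beats * beat_duration_s, 1.0 / frame_rate_hz)
    phase = (t % beat_duration_s) / beat_duration_s
    return VelocityEnvelope(t, _unit_waveform(shape, phase))
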