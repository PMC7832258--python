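"""Spectrogram computation and maximum-velocity envelope tracing.

The tracer implements an integrated-power-percentile estimator: for each
spectrogram frame the noise floor is estimated from the highest-frequency tail
(assumed to lie above any physiological Doppler shift), subtracted, and the
envelope frequency is the lowest bin at which the cumulative noise-corrected
power reaches a configurable fraction (default 0.95) of the frame total.
Frames without appreciable power above the noise floor are reported as zero
velocity and flagged in a quality mask that propagates to beat segmentation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sp_signal

from .errors import InputFormatError, ParameterError
from .physics import DopplerConfig, frequency_to_velocity, velocity_to_frequency

__all__ = [
    "Spectrogram",
    "VelocityEnvelope",
    "compute_spectrogram",
    "trace_max_frequency",
    "trace_envelope",
    "frequency_to_velocity",
    "velocity_to_frequency",
]


@dataclasses.dataclass
class Spectrogram:
    """Short-time power spectrum of a Doppler audio channel.

    ``power`` is linear power, shape (n_frames, n_bins). With the Hann window
    and ``scaling='spectrum'`` used by :func:`compute_spectrogram`, the sum of
    ``power`` over frequency bins equals the mean square of the windowed
    segment (one-sided, window-power normalised), so per-frame totals are
    comparable across frames.
    """

    frame_times: np.ndarray
    frequency_bins: np.ndarray
    power: np.ndarray
    window_length_s: float
    hop_s: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.frequency_bins = np.asarray(self.frequency_bins, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.frame_times.size, self.frequency_bins.size):
            raise InputFormatError("power must have shape (n_frames, n_bins)")
        if np.any(self.power < 0):
            raise InputFormatError("spectrogram power must be non-negative")
        if self.frame_times.size > 1:
            hops = np.diff(self.frame_times)
            if np.any(hops <= 0) or not np.allclose(hops, hops[0], rtol=1e-6):
                raise InputFormatError("frame_times must increase with a uniform hop")


@dataclasses.dataclass
class VelocityEnvelope:
    """Uniformly sampled maximum-velocity time series in cm/s.

    ``quality`` marks frames with usable signal; frames traced as zero because
    nothing rose above the noise floor carry ``quality=False``.
    """

    frame_times: np.ndarray
    velocity_cm_s: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.velocity_cm_s = np.asarray(self.velocity_cm_s, dtype=float)
        if self.frame_times.shape != self.velocity_cm_s.shape:
            raise InputFormatError("frame_times and velocity_cm_s must have equal length")
        if self.frame_times.size and np.any(np.diff(self.frame_times) <= 0):
            raise InputFormatError("frame_times must be strictly increasing")
        if np.any(self.velocity_cm_s < 0):
            raise InputFormatError("velocity must be non-negative")
        if self.quality is None:
            self.quality = np.ones(self.frame_times.size, dtype=bool)
        else:
            self.quality = np.asarray(self.quality, dtype=bool)
            if self.quality.shape != self.frame_times.shape:
                raise InputFormatError("quality mask must match frame_times")

    @property
    def frame_rate_hz(self) -> float:
        if self.frame_times.size < 2:
            raise InputFormatError("envelope too short to define a frame rate")
        return 1.0 / float(np.median(np.diff(self.frame_times)))


def compute_spectrogram(
    audio: np.ndarray,
    sample_rate_hz: float,
    window_length_s: float = 0.010,
    hop_s: float = 0.0025,
) -> Spectrogram:
    """STFT power spectrogram with a Hann window and no edge padding.

    The frame count follows the unpadded sliding-window formula
    ``floor((N - window_samples) / hop_samples) + 1``; frame times are window
    centres.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise InputFormatError("audio must be a single channel (1-D array)")
    if not (hop_s > 0 and window_length_s >= hop_s):
        raise ParameterError("require window_length_s >= hop_s > 0")
    nperseg = int(round(window_length_s * sample_rate_hz))
    hop = int(round(hop_s * sample_rate_hz))
    if nperseg < 2 or hop < 1:
        raise ParameterError("window/hop too short for this sample rate")
    if audio.size < nperseg:
        raise InputFormatError(
            f"audio ({audio.size} samples) is shorter than one window ({nperseg})"
        )
    freqs, times, power = sp_signal.spectrogram(
        audio,
        fs=sample_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        detrend=False,
        scaling="spectrum",
        mode="psd",
    )
    return Spectrogram(
        frame_times=times,
        frequency_bins=freqs,
        power=power.T,
        window_length_s=nperseg / sample_rate_hz,
        hop_s=hop / sample_rate_hz,
    )


def trace_max_frequency(
    spec: Spectrogram,
    percentile: float = 0.95,
    noise_floor_quantile: float = 0.10,
    smooth_frames: int = 5,
    signal_floor_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trace the per-frame maximum Doppler shift (Hz).

    Per frame: the noise floor is the mean power of the top
    ``noise_floor_quantile`` fraction of frequency bins; the traced frequency
    is the lowest frequency at which the cumulative floor-corrected power
    reaches ``percentile`` of the frame total — located at the first crossing
    bin (lower bin on exact ties) and refined by linear interpolation of the
    cumulative within that bin, which removes window-lobe quantisation. Frames
    whose corrected total does not exceed ``signal_floor_factor`` times the
    floor-level power summed over all bins are reported as 0 Hz and masked.
    The traced series is median-filtered over ``smooth_frames`` frames.

    Returns
    -------
    (frequencies, quality) :
        Arrays of length n_frames; ``quality`` is False for masked frames.
    """
    if not (0.0 < percentile < 1.0):
        raise ParameterError("percentile must lie in (0, 1)")
    if not (0.0 < noise_floor_quantile < 1.0):
        raise ParameterError("noise_floor_quantile must lie in (0, 1)")
    if smooth_frames < 1 or smooth_frames % 2 == 0:
        raise ParameterError("smooth_frames must be a positive odd count")

    power = spec.power
    n_frames, n_bins = power.shape
    n_tail = max(1, int(round(noise_floor_quantile * n_bins)))
    floor = power[:, n_bins - n_tail :].mean(axis=1)
    corrected = np.clip(power - floor[:, None], 0.0, None)
    total = corrected.sum(axis=1)
    quality = total > signal_floor_factor * floor * n_bins
    quality &= total > 0

    cum = np.cumsum(corrected, axis=1)
    target = percentile * total
    # lowest frequency where the piecewise-linear cumulative reaches the
    # target: first crossing bin (lower bin on exact ties), refined by linear
    # interpolation within that bin to remove window-lobe quantisation
    reached = cum >= target[:, None]
    idx = reached.argmax(axis=1)
    rows = np.arange(n_frames)
    f_hi = spec.frequency_bins[idx]
    cum_hi = cum[rows, idx]
    idx_lo = np.maximum(idx - 1, 0)
    f_lo = np.where(idx > 0, spec.frequency_bins[idx_lo], f_hi)
    cum_lo = np.where(idx > 0, cum[rows, idx_lo], cum_hi)
    denom = cum_hi - cum_lo
    frac = np.where(denom > 0, (target - cum_lo) / np.where(denom > 0, denom, 1.0), 1.0)
    freqs = f_lo + np.clip(frac, 0.0, 1.0) * (f_hi - f_lo)
    freqs = np.where(quality, freqs, 0.0)
    if smooth_frames > 1 and n_frames >= smooth_frames:
        freqs = sp_signal.medfilt(freqs, kernel_size=smooth_frames)
        freqs = np.where(quality, freqs, 0.0)
    return freqs, quality


def trace_envelope(
    audio: np.ndarray,
    sample_rate_hz: float,
    config: DopplerConfig,
    window_length_s: float = 0.010,
    hop_s: float = 0.0025,
    percentile: float = 0.95,
    noise_floor_quantile: float = 0.10,
    smooth_frames: int = 5,
    signal_floor_factor: float = 1.0,
) -> VelocityEnvelope:
    """Audio channel -> maximum-velocity envelope (cm/s) with quality mask."""
    spec = compute_spectrogram(audio, sample_rate_hz, window_length_s, hop_s)
    freqs, quality = trace_max_frequency(
        spec,
        percentile=percentile,
        noise_floor_quantile=noise_floor_quantile,
        smooth_frames=smooth_frames,
        signal_floor_factor=signal_floor_factor,
    )
    velocity = frequency_to_velocity(freqs, config)
    return VelocityEnvelope(spec.frame_times, velocity, quality)
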