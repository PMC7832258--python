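"""Doppler channel physics: carrier configuration and shift/velocity conversion.

The classical CW Doppler relation links a blood velocity ``v`` (along the beam,
towards the transducer) to an audio-band frequency shift::

    f = 2 * f0 * v * cos(theta) / c

with carrier frequency ``f0``, speed of sound in tissue ``c`` and insonation
angle ``theta``. Velocities are handled in cm/s throughout the package (the
clinical convention); the conversion functions do the m/s bookkeeping.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import ParameterError

__all__ = [
    "DopplerConfig",
    "velocity_to_frequency",
    "frequency_to_velocity",
    "nyquist_velocity_cm_s",
]


@dataclasses.dataclass(frozen=True)
class DopplerConfig:
    """Physical constants of one ultrasound audio channel.

    Parameters
    ----------
    carrier_frequency_hz :
        Transmit frequency ``f0`` in Hz. Default 4 MHz, a typical CW carrier
        for superficial vessels.
    speed_of_sound_m_s :
        Speed of sound in soft tissue, m/s. Default 1540.
    insonation_angle_deg :
        Angle between the beam and the flow direction, degrees. Must lie in
        [0, 90). Default 0 (flow along the beam).
    audio_sample_rate_hz :
        Sample rate of the demodulated audio signal, Hz. Default 44100 for
        plain WAV compatibility.
    """

    carrier_frequency_hz: float = 4.0e6
    speed_of_sound_m_s: float = 1540.0
    insonation_angle_deg: float = 0.0
    audio_sample_rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        for name in dataclasses.fields(self):
            value = getattr(self, name.name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ParameterError(f"{name.name} must be a finite number, got {value!r}")
        if self.carrier_frequency_hz <= 0:
            raise ParameterError("carrier_frequency_hz must be > 0")
        if self.speed_of_sound_m_s <= 0:
            raise ParameterError("speed_of_sound_m_s must be > 0")
        if not (0.0 <= self.insonation_angle_deg < 90.0):
            raise ParameterError(
                "insonation_angle_deg must lie in [0, 90); "
                f"got {self.insonation_angle_deg} (beam perpendicular to flow "
                "leaves the Doppler geometry undefined)"
            )
        if self.audio_sample_rate_hz <= 0:
            raise ParameterError("audio_sample_rate_hz must be > 0")

    @property
    def angle_cosine(self) -> float:
        return math.cos(math.radians(self.insonation_angle_deg))


def velocity_to_frequency(velocity_cm_s, config: DopplerConfig):
    """Doppler shift (Hz) of a blood velocity given in cm/s."""
    v_m_s = np.asarray(velocity_cm_s, dtype=float) / 100.0
    f = 2.0 * config.carrier_frequency_hz * v_m_s * config.angle_cosine / config.speed_of_sound_m_s
    return f if f.ndim else float(f)


def frequency_to_velocity(frequency_hz, config: DopplerConfig):
    """Blood velocity (cm/s) corresponding to a Doppler shift in Hz.

    Inverse of :func:`velocity_to_frequency`: ``v = f * c / (2 * f0 * cos(theta))``.
    """
    f = np.asarray(frequency_hz, dtype=float)
    v_m_s = f * config.speed_of_sound_m_s / (2.0 * config.carrier_frequency_hz * config.angle_cosine)
    v = v_m_s * 100.0
    return v if v.ndim else float(v)


def nyquist_velocity_cm_s(config: DopplerConfig) -> float:
    """Largest velocity representable below the audio Nyquist frequency."""
    return frequency_to_velocity(config.audio_sample_rate_hz / 2.0, config)
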