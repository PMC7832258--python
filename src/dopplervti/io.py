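"""File formats and run configuration.

All tabular artifacts are plain CSV with documented headers; every analysis
output written by the pipeline embeds the run-configuration hash, either as a
leading ``# config_hash=...`` comment line (CSV) or a ``config_hash`` field
(JSON). Audio is 16-bit PCM WAV (channel 0 carotid, channel 1 aortic),
peak-normalised on write. Floats are written with 17 significant digits so
CSV round trips are exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .beats import BeatTable
from .envelope import VelocityEnvelope
from .errors import InputFormatError, ParameterError
from .physics import DopplerConfig
from .sim import PRESET_NAMES, SVSeries

__all__ = [
    "RunConfig",
    "write_wav",
    "read_wav",
    "write_envelope_csv",
    "read_envelope_csv",
    "write_beats_csv",
    "write_sv_csv",
    "read_sv_csv",
    "write_json",
]

_FLOAT_FMT = "%.17g"


@dataclasses.dataclass
class RunConfig:
    """Full configuration of an end-to-end cohort run.

    Round-trips losslessly through YAML; :meth:`config_hash` is a stable
    digest of the canonical JSON form, embedded in every output.
    """

    preset: str = "paper_cohort"
    n_responders: int = 8
    n_controls: int = 8
    seed: int = 42
    snr_db: float = 20.0
    # Doppler channel
    carrier_frequency_hz: float = 4.0e6
    speed_of_sound_m_s: float = 1540.0
    insonation_angle_deg: float = 0.0
    audio_sample_rate_hz: float = 44100.0
    n_scatterers: int = 64
    # envelope estimator
    window_length_s: float = 0.010
    hop_s: float = 0.0025
    percentile: float = 0.95
    noise_floor_quantile: float = 0.10
    smooth_frames: int = 5
    # beat detector
    refractory_s: float = 0.3
    min_prominence_fraction: float = 0.25
    # protocol / detection
    phase_durations_s: tuple[float, float, float, float] = (15.0, 15.0, 15.0, 15.0)
    detection_threshold_pct: float = 10.0
    frame_rate_hz: float = 400.0
    out_dir: str = "dopplervti_run"

    def __post_init__(self) -> None:
        if self.preset not in PRESET_NAMES:
            raise ParameterError(f"unknown preset {self.preset!r}; choose from {PRESET_NAMES}")
        self.phase_durations_s = tuple(float(d) for d in self.phase_durations_s)

    def doppler_config(self) -> DopplerConfig:
        return DopplerConfig(
            carrier_frequency_hz=self.carrier_frequency_hz,
            speed_of_sound_m_s=self.speed_of_sound_m_s,
            insonation_angle_deg=self.insonation_angle_deg,
            audio_sample_rate_hz=self.audio_sample_rate_hz,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phase_durations_s"] = list(self.phase_durations_s)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise InputFormatError(f"{path}: config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Digest of the analysis-relevant configuration (out_dir excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        canonical = json.dumps(d, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# WAV


def write_wav(path: str | Path, audio: np.ndarray, sample_rate_hz: float) -> None:
    """Write float audio as peak-normalised 16-bit PCM WAV."""
    audio = np.asarray(audio, dtype=np.float64)
    peak = float(np.max(np.abs(audio))) if audio.size else 0.0
    scale = 0.95 * 32767.0 / peak if peak > 0 else 0.0
    pcm = np.round(audio * scale).astype(np.int16)
    wavfile.write(str(path), int(round(sample_rate_hz)), pcm)


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file as float in [-1, 1]; returns (samples, sample_rate)."""
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    else:
        data = data.astype(np.float64)
    return data, float(rate)


# ---------------------------------------------------------------------------
# CSV


def _write_csv(path: Path, df: pd.DataFrame, config_hash: str | None) -> None:
    with open(path, "w", newline="") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise InputFormatError(f"{path}: file contains no data rows")
    return df


def write_envelope_csv(
    path: str | Path, env: VelocityEnvelope, config_hash: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "time_s": env.frame_times,
            "velocity_cm_s": env.velocity_cm_s,
            "quality_flag": env.quality.astype(int),
        }
    )
    _write_csv(Path(path), df, config_hash)


def read_envelope_csv(path: str | Path) -> VelocityEnvelope:
    df = _read_csv(path, ("time_s", "velocity_cm_s"))
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise InputFormatError(
            f"{path}: time_s not strictly increasing at data row {int(bad[0]) + 2}"
        )
    quality = (
        df["quality_flag"].to_numpy(dtype=bool) if "quality_flag" in df.columns else None
    )
    return VelocityEnvelope(t, df["velocity_cm_s"].to_numpy(dtype=float), quality)


def write_beats_csv(path: str | Path, beats: BeatTable, config_hash: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "onset_s": beats.onset_times_s,
            "rr_s": beats.rr_s,
            "hr_bpm": beats.hr_bpm,
            "vti_cm": beats.vti_cm,
            "peak_cm_s": beats.peak_cm_s,
            "kept_flag": beats.kept.astype(int),
        }
    )
    _write_csv(Path(path), df, config_hash)


def write_sv_csv(path: str | Path, sv: SVSeries, config_hash: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "time_s": sv.sample_times_s,
            "sv_ml": sv.sv_ml,
            "map_mmhg": sv.map_mmhg,
            "sbp_mmhg": sv.sbp_mmhg,
        }
    )
    _write_csv(Path(path), df, config_hash)


def read_sv_csv(path: str | Path) -> SVSeries:
    df = _read_csv(path, ("time_s", "sv_ml", "map_mmhg", "sbp_mmhg"))
    t = df["time_s"].to_numpy(dtype=float)
    interval = float(t[1] - t[0]) if t.size > 1 else 20.0
    return SVSeries(
        t,
        df["sv_ml"].to_numpy(dtype=float),
        df["map_mmhg"].to_numpy(dtype=float),
        df["sbp_mmhg"].to_numpy(dtype=float),
        update_interval_s=interval,
    )


def write_json(path: str | Path, payload: dict, config_hash: str | None = None) -> None:
    if config_hash is not None:
        payload = {"config_hash": config_hash, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n")
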