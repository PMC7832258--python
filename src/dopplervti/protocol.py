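"""Valsalva protocol windows, window aggregation, and the Doppler Shock Index.

The analysis windows follow the study convention for a four-phase protocol:
T1 is a 5-s baseline window ending 5 s before the inspiratory hold, T2 the
terminal 5 s of the inspiratory hold, and T3 the terminal 5 s of the final
recovery phase. Beat membership in a window is by onset time in the half-open
interval. The Doppler Shock Index (DSI) is heart rate divided by carotid VTI
(bpm/cm) — the shock index (HR / systolic blood pressure) with the pressure
replaced by the patch-derived VTI.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .beats import BeatTable
from .errors import ConfigurationError, InputFormatError, MissingWindowError, ParameterError
from .sim import SVSeries

__all__ = [
    "ProtocolWindows",
    "SubjectResult",
    "define_windows",
    "window_mean",
    "beat_window_mean",
    "compute_dsi",
    "compute_si",
    "percent_change",
    "sv_windows",
    "analyze_subject",
    "QUANTITIES",
    "CHANGE_PAIRS",
]

QUANTITIES = ("carotid_vti", "aortic_vti", "hr", "dsi", "si", "sv", "map")
CHANGE_PAIRS = (("T1", "T2"), ("T2", "T3"), ("T1", "T3"))


@dataclasses.dataclass(frozen=True)
class ProtocolWindows:
    """Three ordered, non-overlapping half-open time intervals in seconds."""

    t1: tuple[float, float]
    t2: tuple[float, float]
    t3: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (a, b) in zip(("t1", "t2", "t3"), (self.t1, self.t2, self.t3)):
            if not b > a:
                raise ParameterError(f"window {name} must have positive length")
        if not (self.t1[1] <= self.t2[0] and self.t2[1] <= self.t3[0]):
            raise ParameterError("windows must be ordered and non-overlapping")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"T1": self.t1, "T2": self.t2, "T3": self.t3}


def define_windows(phase_durations_s) -> ProtocolWindows:
    """Derive T1/T2/T3 from the four protocol phase durations.

    With the default 15-s phases this gives T1 = [5, 10), T2 = [25, 30),
    T3 = [55, 60). Every phase must be at least 5 s long.
    """
    phases = tuple(float(d) for d in phase_durations_s)
    if len(phases) != 4 or any(d <= 0 for d in phases):
        raise ConfigurationError("need four positive phase durations")
    if any(d < 5.0 for d in phases):
        raise ConfigurationError("every protocol phase must last at least 5 s")
    d1, d2, d3, d4 = phases
    t1_start = min(5.0, d1 - 5.0)
    hold_end = d1 + d2
    total = d1 + d2 + d3 + d4
    return ProtocolWindows(
        t1=(t1_start, t1_start + 5.0),
        t2=(hold_end - 5.0, hold_end),
        t3=(total - 5.0, total),
    )


def beat_window_mean(onsets: np.ndarray, values: np.ndarray, interval) -> float:
    """Unweighted mean of per-beat values with onset in the half-open interval."""
    onsets = np.asarray(onsets, dtype=float)
    values = np.asarray(values, dtype=float)
    a, b = interval
    mask = (onsets >= a) & (onsets < b)
    if not np.any(mask):
        raise MissingWindowError(f"no beats with onset in [{a}, {b})")
    return float(np.mean(values[mask]))


def window_mean(beats: BeatTable, interval) -> dict[str, float]:
    """Mean VTI, HR and peak velocity over kept beats in the window."""
    a, b = interval
    mask = (beats.onset_times_s >= a) & (beats.onset_times_s < b) & beats.kept
    if not np.any(mask):
        raise MissingWindowError(f"no kept beats with onset in [{a}, {b})")
    return {
        "vti": float(np.mean(beats.vti_cm[mask])),
        "hr": float(np.mean(beats.hr_bpm[mask])),
        "peak": float(np.mean(beats.peak_cm_s[mask])),
        "n_beats": int(mask.sum()),
    }


def compute_dsi(hr_bpm: float, vti_cm: float) -> float:
    """Doppler Shock Index: heart rate / carotid VTI (bpm/cm)."""
    if not vti_cm > 0:
        raise ParameterError("vti_cm must be > 0")
    return hr_bpm / vti_cm


def compute_si(hr_bpm: float, sbp_mmhg: float) -> float:
    """Traditional shock index: heart rate / systolic blood pressure."""
    if not sbp_mmhg > 0:
        raise ParameterError("sbp_mmhg must be > 0")
    return hr_bpm / sbp_mmhg


def percent_change(a: float, b: float) -> float:
    """Percent change from ``a`` to ``b``: ``100 * (b - a) / a``."""
    if a == 0:
        raise ParameterError("percent change undefined for a baseline of 0")
    return 100.0 * (b - a) / a


def sv_windows(sv: SVSeries, protocol_duration_s: float) -> dict[str, int]:
    """Window sample indices for the slow monitor channel.

    T1 is the sample immediately before the protocol onset (t <= 0), T2 the
    minimum-SV sample in (0, protocol_duration] (earliest on ties) — the peak
    Valsalva effect — and T3 the last sample at/before the protocol end.
    """
    times = sv.sample_times_s
    pre = np.flatnonzero(times <= 0.0)
    if pre.size == 0:
        raise InputFormatError("missing pre-onset SV sample (no sample with t <= 0)")
    i1 = int(pre[-1])
    during = np.flatnonzero((times > 0.0) & (times <= protocol_duration_s))
    if during.size == 0:
        raise InputFormatError("SV series does not cover the protocol")
    i2 = int(during[np.argmin(sv.sv_ml[during])])  # argmin takes the earliest tie
    at_end = np.flatnonzero(times <= protocol_duration_s)
    i3 = int(at_end[-1])
    return {"T1": i1, "T2": i2, "T3": i3}


@dataclasses.dataclass
class SubjectResult:
    """Per-window means and percent changes for one subject.

    ``windows`` maps window name -> quantity -> value; ``changes`` maps
    "T1T2" / "T2T3" / "T1T3" -> quantity -> percent change. Quantities that
    could not be computed (missing channel, empty window) are NaN and the
    reason is recorded in ``flags``.
    """

    subject_id: str
    windows: dict[str, dict[str, float]]
    changes: dict[str, dict[str, float]]
    flags: list[str] = dataclasses.field(default_factory=list)

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {"subject_id": self.subject_id}
        for wname, values in self.windows.items():
            for q, v in values.items():
                row[f"{wname}_{q}"] = v
        for pair, values in self.changes.items():
            for q, v in values.items():
                row[f"{pair}_{q}_pct"] = v
        row["flags"] = ";".join(self.flags)
        return row


def analyze_subject(
    carotid_beats: BeatTable,
    windows: ProtocolWindows,
    aortic_beats: BeatTable | None = None,
    sv_series: SVSeries | None = None,
    subject_id: str = "subject",
    dsi_mode: str = "window_mean",
) -> SubjectResult:
    """Compute per-window hemodynamics and percent changes for one subject.

    ``dsi_mode`` selects whether the window DSI is the ratio of window-mean
    HR to window-mean VTI (``"window_mean"``, the reporting convention) or
    the mean of per-beat HR/VTI ratios (``"per_beat"``).
    """
    if dsi_mode not in ("window_mean", "per_beat"):
        raise ParameterError("dsi_mode must be 'window_mean' or 'per_beat'")
    flags: list[str] = []
    wdict = windows.as_dict()
    duration = wdict["T3"][1]
    sv_idx: dict[str, int] | None = None
    if sv_series is not None:
        sv_idx = sv_windows(sv_series, duration)

    per_window: dict[str, dict[str, float]] = {}
    for wname, interval in wdict.items():
        values = {q: math.nan for q in QUANTITIES}
        try:
            car = window_mean(carotid_beats, interval)
            values["carotid_vti"] = car["vti"]
            values["hr"] = car["hr"]
            if dsi_mode == "window_mean":
                values["dsi"] = compute_dsi(car["hr"], car["vti"])
            else:
                a, b = interval
                m = (
                    (carotid_beats.onset_times_s >= a)
                    & (carotid_beats.onset_times_s < b)
                    & carotid_beats.kept
                )
                values["dsi"] = float(
                    np.mean(carotid_beats.hr_bpm[m] / carotid_beats.vti_cm[m])
                )
        except MissingWindowError:
            flags.append(f"{wname}: no kept carotid beats")
        if aortic_beats is not None:
            try:
                values["aortic_vti"] = window_mean(aortic_beats, interval)["vti"]
            except MissingWindowError:
                flags.append(f"{wname}: no kept aortic beats")
        if sv_series is not None and sv_idx is not None:
            i = sv_idx[wname]
            values["sv"] = float(sv_series.sv_ml[i])
            values["map"] = float(sv_series.map_mmhg[i])
            if math.isfinite(values["hr"]):
                values["si"] = compute_si(values["hr"], float(sv_series.sbp_mmhg[i]))
        per_window[wname] = values

    changes: dict[str, dict[str, float]] = {}
    for wa, wb in CHANGE_PAIRS:
        pair = f"{wa}{wb}"
        changes[pair] = {}
        for q in QUANTITIES:
            a = per_window[wa][q]
            b = per_window[wb][q]
            if math.isfinite(a) and math.isfinite(b) and a != 0:
                changes[pair][q] = percent_change(a, b)
            else:
                changes[pair][q] = math.nan
    return SubjectResult(subject_id=subject_id, windows=per_window, changes=changes, flags=flags)
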