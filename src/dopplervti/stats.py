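"""Statistical layer: paired t-tests and threshold detection metrics.

The detection question mirrors the study design: a subject is truly positive
when the reference variable (descending-aortic VTI, or stroke volume) fell by
at least the clinical threshold (10%), and a predictor — carotid VTI fall,
DSI rise, shock-index rise — is evaluated by its sensitivity and specificity
at a decision threshold on its own percent change.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sp_stats

from .errors import DegenerateTestError, InputFormatError, ParameterError

__all__ = [
    "TTestResult",
    "DetectionResult",
    "paired_t_test",
    "detection_metrics",
    "sweep_thresholds",
    "best_threshold",
]


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclasses.dataclass
class DetectionResult:
    """Confusion-matrix summary of one predictor at one decision threshold.

    ``separation_margin`` is the minimum positive-class directional magnitude
    minus the maximum negative-class directional magnitude (percentage
    points); it is positive iff the classes are perfectly separable.
    Sensitivity/specificity are NaN when the corresponding class is empty.
    """

    truth_labels: np.ndarray
    predictor_values: np.ndarray
    decision_threshold: float
    direction: str
    sensitivity: float
    specificity: float
    separation_margin: float
    tp: int
    fp: int
    tn: int
    fn: int


def paired_t_test(x, y) -> TTestResult:
    """Two-tailed paired Student t-test on per-subject values.

    The statistic is ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = y - x``
    and the sample standard deviation (n-1 denominator); df = n - 1. Raises
    :class:`DegenerateTestError` when all differences are identical (zero
    variance, infinite or undefined t).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputFormatError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise InputFormatError("need at least 2 pairs")
    d = y - x
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateTestError("all paired differences are identical; t is undefined")
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(sp_stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p)


def _directional(predictor: np.ndarray, direction: str) -> np.ndarray:
    if direction == "fall":
        return -predictor
    if direction == "rise":
        return predictor.copy()
    raise ParameterError("direction must be 'fall' or 'rise'")


def detection_metrics(
    truth, predictor, threshold: float, direction: str = "fall"
) -> DetectionResult:
    """Sensitivity/specificity of a percent-change predictor at a threshold.

    A subject is predicted positive when its change crosses the threshold in
    the stated direction: for ``direction="fall"`` when change <= -threshold,
    for ``"rise"`` when change >= +threshold.
    """
    truth = np.asarray(truth, dtype=bool)
    predictor = np.asarray(predictor, dtype=float)
    if truth.shape != predictor.shape or truth.ndim != 1:
        raise InputFormatError("truth and predictor must be 1-D arrays of equal length")
    s = _directional(predictor, direction)
    predicted = s >= threshold
    tp = int(np.sum(predicted & truth))
    fn = int(np.sum(~predicted & truth))
    tn = int(np.sum(~predicted & ~truth))
    fp = int(np.sum(predicted & ~truth))
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    specificity = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    if truth.any() and (~truth).any():
        margin = float(np.min(s[truth]) - np.max(s[~truth]))
    else:
        margin = math.nan
    return DetectionResult(
        truth_labels=truth,
        predictor_values=predictor,
        decision_threshold=float(threshold),
        direction=direction,
        sensitivity=sensitivity,
        specificity=specificity,
        separation_margin=margin,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def sweep_thresholds(truth, predictor, direction: str = "fall") -> list[dict[str, float]]:
    """Evaluate sensitivity/specificity at every informative threshold.

    Thresholds are the midpoints between consecutive sorted directional
    predictor values, plus one threshold below the minimum and one above the
    maximum. Returns a list of ``{"threshold", "sensitivity", "specificity"}``
    rows in increasing threshold order.
    """
    truth = np.asarray(truth, dtype=bool)
    predictor = np.asarray(predictor, dtype=float)
    if not truth.any() or truth.all():
        raise InputFormatError("threshold sweep requires both classes to be non-empty")
    s = np.sort(np.unique(_directional(predictor, direction)))
    thresholds = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]])
    rows = []
    for thr in thresholds:
        m = detection_metrics(truth, predictor, thr, direction)
        rows.append(
            {
                "threshold": float(thr),
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
            }
        )
    return rows


def best_threshold(truth, predictor, direction: str = "fall") -> DetectionResult:
    """Detection metrics at the Youden-optimal threshold.

    Maximises J = sensitivity + specificity - 1 over the sweep; ties are
    broken towards the larger threshold (the more conservative detector).
    """
    rows = sweep_thresholds(truth, predictor, direction)
    best = max(rows, key=lambda r: (r["sensitivity"] + r["specificity"], r["threshold"]))
    return detection_metrics(truth, predictor, best["threshold"], direction)
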