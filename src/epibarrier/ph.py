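"""Ratiometric intracellular-pH calibration and conversion.

BCECF-loaded cells report intracellular pH through the 495/436 nm
excitation-ratio of their emission.  The ratio is mapped to pH with an
in-situ calibration: cells are clamped to known pH values with
high-potassium/nigericin solutions and the mean ratio at each anchor pH is
recorded.  Over the usual 6.0-8.4 working range the relationship is close
to linear, so the default calibration model is a least-squares line

    ratio = a * pH + b,

inverted as ``pH = (ratio - b) / a``.  Resting pH is the baseline-window
mean ratio of each ROI converted through the fitted curve; group
statistics are taken across ROIs (n = number of ROIs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CalibrationCurve",
    "RatioTrace",
    "fit_calibration",
    "ratio_to_ph",
    "resting_ph",
    "group_resting_ph",
]

#: pH range spanned by standard high-K+/nigericin calibration solutions.
CALIBRATION_PH_RANGE = (6.0, 8.4)
DEFAULT_BASELINE_WINDOW_S = (0.0, 60.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear ratio-vs-pH calibration with validity range."""

    slope: float
    intercept: float
    residual_sd: float
    ph_range: tuple[float, float]
    anchors: tuple = ()

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope is zero: mapping is not invertible")


@dataclass(frozen=True)
class RatioTrace:
    """One ROI's 495/436 emission-ratio time series."""

    roi: str
    time_s: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("time and ratio must be 1-D arrays of equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if (r <= 0).any():
            raise ValueError("emission ratios must be positive")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "ratio", r)


def fit_calibration(ph_values, ratios) -> CalibrationCurve:
    """Least-squares linear fit of emission ratio on anchor pH.

    Requires at least two anchors at distinct pH.  A warning is emitted if
    the anchor ratios are not monotone in pH (noise can explain small
    inversions, but the fitted mapping must stay strictly monotone) or if
    anchors fall outside the 6.0-8.4 calibration range.
    """
    ph = np.asarray(ph_values, dtype=float)
    ratio = np.asarray(ratios, dtype=float)
    if ph.size < 2:
        raise ValueError("need at least 2 calibration anchors")
    if ph.size != ratio.size:
        raise ValueError("pH and ratio arrays differ in length")
    if np.ptp(ph) == 0:
        raise ValueError("calibration anchors have coincident pH values")
    lo, hi = CALIBRATION_PH_RANGE
    if ph.min() < lo or ph.max() > hi:
        warnings.warn(
            f"calibration anchors outside the standard pH range [{lo}, {hi}]",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(ph)
    if not (np.all(np.diff(ratio[order]) > 0) or np.all(np.diff(ratio[order]) < 0)):
        warnings.warn("calibration anchors are not monotone in pH", RuntimeWarning, stacklevel=2)
    res = sps.linregress(ph, ratio)
    fitted = res.intercept + res.slope * ph
    dof = max(ph.size - 2, 1)
    residual_sd = float(np.sqrt(np.sum((ratio - fitted) ** 2) / dof))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        ph_range=(float(ph.min()), float(ph.max())),
        anchors=tuple(zip(ph.tolist(), ratio.tolist())),
    )


def ratio_to_ph(curve: CalibrationCurve, ratio) -> np.ndarray | float:
    """Invert the calibration: pH = (ratio - intercept) / slope.

    Values falling outside the fitted validity range are flagged with a
    warning (extrapolation beyond the calibrated anchors).
    """
    ph = (np.asarray(ratio, dtype=float) - curve.intercept) / curve.slope
    lo, hi = curve.ph_range
    if np.any(ph < lo) or np.any(ph > hi):
        warnings.warn(
            f"converted pH outside calibrated range [{lo:.2f}, {hi:.2f}]: extrapolating",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(ph) if np.isscalar(ratio) else ph


def resting_ph(
    trace: RatioTrace,
    curve: CalibrationCurve,
    baseline_window_s: tuple[float, float] = DEFAULT_BASELINE_WINDOW_S,
) -> float:
    """Resting intracellular pH of one ROI.

    The mean emission ratio over the baseline window (default: first 60 s,
    i.e. before any calibration or treatment solutions arrive) converted
    through the calibration curve.
    """
    t0, t1 = baseline_window_s
    sel = (trace.time_s >= t0) & (trace.time_s <= t1)
    if not sel.any():
        raise ValueError(f"baseline window [{t0}, {t1}] s contains no samples")
    return float(ratio_to_ph(curve, float(trace.ratio[sel].mean())))


def group_resting_ph(
    traces: list[RatioTrace],
    curve: CalibrationCurve,
    baseline_window_s: tuple[float, float] = DEFAULT_BASELINE_WINDOW_S,
) -> pd.DataFrame:
    """Per-ROI resting pH plus a summary row (mean +- sd across ROIs)."""
    if not traces:
        raise ValueError("no traces supplied")
    rows = [
        {"roi": tr.roi, "ph": resting_ph(tr, curve, baseline_window_s)} for tr in traces
    ]
    df = pd.DataFrame(rows)
    df.attrs["mean"] = float(df["ph"].mean())
    df.attrs["sd"] = float(df["ph"].std(ddof=1)) if len(df) > 1 else 0.0
    df.attrs["n"] = len(df)
    return df
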