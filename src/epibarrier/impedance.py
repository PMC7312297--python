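"""Real-time impedance kinetics: cell index, normalization, viability calls.

Impedance-based real-time cell analysis reports a dimensionless *cell
index* CI = (Rn - Rb)/15, where Rn is the well impedance with cells and Rb
the background impedance of the well with medium alone (single-frequency
10 kHz reading).  Treatments are applied at the plateau phase of growth;
traces are normalized to the last pre-treatment sample so that treated and
control wells are directly comparable, and kinetic windows after treatment
are summarized for viability calls against a cytotoxic reference
(detergent-lysed wells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImpedanceTrace",
    "CI_SCALE_OHM",
    "compute_cell_index",
    "normalize_cell_index",
    "summarize_window",
    "viability_call",
]

#: Instrument scale factor in CI = (Rn - Rb) / 15.
CI_SCALE_OHM = 15.0

#: Default post-treatment windows (hours after treatment): the transient
#: window where temporary effects show, and the terminal window used for
#: recovery/lethality calls.
TRANSIENT_WINDOW_H = (6.0, 15.0)
TERMINAL_WINDOW_H = (16.0, 24.0)


@dataclass(frozen=True)
class ImpedanceTrace:
    """Time-stamped well impedance with background and treatment time."""

    time_h: np.ndarray
    impedance_ohm: np.ndarray
    rb_ohm: float
    treatment_h: float = 0.0
    well: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        r = np.asarray(self.impedance_ohm, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("time and impedance must be 1-D arrays of equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if self.rb_ohm < 0:
            raise ValueError(f"background impedance must be >= 0, got {self.rb_ohm}")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "impedance_ohm", r)


def compute_cell_index(trace: ImpedanceTrace) -> np.ndarray:
    """Cell-index series CI(t) = (Rn(t) - Rb) / 15."""
    return (trace.impedance_ohm - trace.rb_ohm) / CI_SCALE_OHM


def normalize_cell_index(
    ci: np.ndarray, time_h: np.ndarray, treatment_h: float
) -> np.ndarray:
    """Divide a CI series by its value at the last sample <= treatment time.

    The anchor sample maps to exactly 1.0.  Requires a positive anchor CI
    (a dead or empty well cannot be normalized).
    """
    ci = np.asarray(ci, dtype=float)
    time_h = np.asarray(time_h, dtype=float)
    pre = np.nonzero(time_h <= treatment_h)[0]
    if pre.size == 0:
        raise ValueError("no sample at or before the treatment time")
    anchor = ci[pre[-1]]
    if anchor <= 0:
        raise ValueError(
            f"cell index at the pre-treatment anchor is {anchor:g}; "
            "cannot normalize a dead or empty well"
        )
    return ci / anchor


def summarize_window(
    series: np.ndarray, time_h: np.ndarray, window: tuple[float, float]
) -> tuple[float, float]:
    """Arithmetic mean and sd of samples with t in [t_start, t_end]."""
    t0, t1 = window
    series = np.asarray(series, dtype=float)
    time_h = np.asarray(time_h, dtype=float)
    sel = (time_h >= t0) & (time_h <= t1)
    if not sel.any():
        raise ValueError(f"no samples in window [{t0}, {t1}] h")
    vals = series[sel]
    return float(vals.mean()), float(vals.std(ddof=0))


@dataclass(frozen=True)
class _CallConfig:
    # Deviation from control beyond which a window counts as an effect,
    # and the margin above the cytotoxic reference that still counts as
    # lethal.  Qualitative published calls give no numbers; these defaults
    # are explicit and configurable.
    effect_tol: float = 0.20
    lethal_margin: float = 0.10
    transient_window_h: tuple = TRANSIENT_WINDOW_H
    terminal_window_h: tuple = TERMINAL_WINDOW_H


def viability_call(
    norm_ci: np.ndarray,
    time_h: np.ndarray,
    treatment_h: float = 0.0,
    *,
    lethal_threshold: float | None = None,
    reference_norm_ci: np.ndarray | None = None,
    reference_time_h: np.ndarray | None = None,
    config: _CallConfig = _CallConfig(),
) -> str:
    """Classify a normalized trace as ``viable``, ``transient_effect`` or ``lethal``.

    ``lethal`` — the terminal-window mean is at or below the lethality
    threshold (either ``lethal_threshold`` directly, or the terminal mean
    of a cytotoxic reference trace plus a small margin).
    ``transient_effect`` — the transient window deviates from control
    (|mean - 1| > tolerance) but the terminal window recovers to within
    tolerance of 1.  Otherwise ``viable``.

    Windows are interpreted as hours after ``treatment_h``.
    """
    if lethal_threshold is None:
        if reference_norm_ci is None:
            raise ValueError("supply either lethal_threshold or a reference trace")
        rt = reference_time_h if reference_time_h is not None else time_h
        ref_mean, _ = summarize_window(
            reference_norm_ci,
            np.asarray(rt, float) - treatment_h,
            config.terminal_window_h,
        )
        lethal_threshold = ref_mean * (1.0 + config.lethal_margin)

    t_rel = np.asarray(time_h, dtype=float) - treatment_h
    term_mean, _ = summarize_window(norm_ci, t_rel, config.terminal_window_h)
    if term_mean <= lethal_threshold:
        return "lethal"
    trans_mean, _ = summarize_window(norm_ci, t_rel, config.transient_window_h)
    transient_hit = abs(trans_mean - 1.0) > config.effect_tol
    terminal_recovered = abs(term_mean - 1.0) <= config.effect_tol
    if transient_hit and terminal_recovered:
        return "transient_effect"
    return "viable"
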