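"""Fixation screening, microsaccade detection, main sequence, pupil metrics.

Microsaccades are detected with the classic data-driven velocity-threshold
method: 2D velocity from a +-2-sample weighted central difference, a robust
per-axis velocity SD (median-based), an elliptic threshold at ``lambda``
robust SDs, a minimum event duration, and merging of events separated by
less than ``merge_gap``. The threshold multiplier (6), minimum duration
(10 ms) and kernel are the method's canonical values and are configurable.
Detection is monocular and runs on blink-free segments (traces are split at
NaN runs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "EyeTrace",
    "Microsaccade",
    "EyeParams",
    "MainSequence",
    "detect_fixation_breaks",
    "detect_microsaccades",
    "main_sequence",
    "pupil_cv",
    "pupil_cv_subject",
]


@dataclass
class EyeTrace:
    """Uniformly sampled gaze and pupil trace; NaN runs mark blinks."""

    time: np.ndarray      # s re stimulus onset
    x: np.ndarray         # deg
    y: np.ndarray         # deg
    pupil: np.ndarray     # arbitrary units
    true_events: Tuple = ()   # synthetic ground truth, when generated


@dataclass(frozen=True)
class Microsaccade:
    onset: float          # s
    offset: float         # s
    peak_velocity: float  # deg/s
    max_displacement: float  # deg

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must follow onset")
        if self.peak_velocity <= 0:
            raise ValueError("peak velocity must be positive")


@dataclass
class EyeParams:
    lam: float = 6.0                      # velocity-threshold multiplier
    min_duration: float = 0.01            # s
    merge_gap: float = 0.02               # s
    fixation_window: float = 5.0          # deg, full width of the square window
    analysis_window: Tuple[float, float] = (-0.5, 0.75)

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.fixation_window <= 0:
            raise ValueError("lam and fixation_window must be positive")


@dataclass
class MainSequence:
    log_displacement: np.ndarray
    log_peak_velocity: np.ndarray
    rate: float                           # events per second of analyzed data


def _window_mask(time: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    return (time >= window[0] - 1e-9) & (time <= window[1] + 1e-9)


def detect_fixation_breaks(trace: EyeTrace, params: EyeParams | None = None) -> bool:
    """True if the repeat must be rejected: a blink (NaN) or an excursion
    outside the square fixation window within the analysis window."""
    params = params or EyeParams()
    m = _window_mask(trace.time, params.analysis_window)
    if not m.any():
        raise ValueError("trace does not cover the analysis window")
    x, y, p = trace.x[m], trace.y[m], trace.pupil[m]
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(p).any():
        return True
    half = params.fixation_window / 2.0
    return bool((np.abs(x) > half).any() or (np.abs(y) > half).any())


def _velocity(x: np.ndarray, dt: float) -> np.ndarray:
    """+-2-sample weighted central difference; endpoints get shorter kernels."""
    v = np.empty_like(x)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt)
    v[1] = (x[2] - x[0]) / (2 * dt)
    v[-2] = (x[-1] - x[-3]) / (2 * dt)
    v[0] = (x[1] - x[0]) / dt
    v[-1] = (x[-1] - x[-2]) / dt
    return v


def _robust_sd(v: np.ndarray) -> float:
    sd = np.sqrt(np.median(v**2) - np.median(v) ** 2)
    return float(max(sd, 1e-12))


def detect_microsaccades(trace: EyeTrace, params: EyeParams | None = None) -> List[Microsaccade]:
    params = params or EyeParams()
    m = _window_mask(trace.time, params.analysis_window)
    t = trace.time[m]
    x = trace.x[m]
    y = trace.y[m]
    if t.size < 5:
        raise ValueError("trace too short for the velocity kernel")
    dt = float(np.median(np.diff(t)))

    good = ~(np.isnan(x) | np.isnan(y))
    events: List[Microsaccade] = []
    # split into blink-free segments
    edges = np.flatnonzero(np.diff(good.astype(int)))
    starts = [0] + (edges + 1).tolist()
    for s, e in zip(starts, starts[1:] + [t.size]):
        if not good[s]:
            continue
        if e - s < 5:
            continue  # shorter than the velocity kernel
        events.extend(_detect_segment(t[s:e], x[s:e], y[s:e], dt, params))
    return events


def _detect_segment(t, x, y, dt, params: EyeParams) -> List[Microsaccade]:
    vx = _velocity(x, dt)
    vy = _velocity(y, dt)
    tx = params.lam * _robust_sd(vx)
    ty = params.lam * _robust_sd(vy)
    crit = (vx / tx) ** 2 + (vy / ty) ** 2 > 1.0

    runs = []
    i = 0
    while i < crit.size:
        if crit[i]:
            j = i
            while j + 1 < crit.size and crit[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge runs closer than merge_gap
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1]) * dt < params.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    out = []
    min_samp = max(1, int(round(params.min_duration / dt)))
    for i0, i1 in merged:
        if i1 - i0 + 1 < min_samp:
            continue
        sl = slice(i0, i1 + 1)
        pv = float(np.max(np.hypot(vx[sl], vy[sl])))
        disp = float(np.max(np.hypot(x[sl] - x[i0], y[sl] - y[i0])))
        out.append(Microsaccade(onset=float(t[i0]), offset=float(t[i1]),
                                peak_velocity=pv, max_displacement=max(disp, 1e-9)))
    return out


def main_sequence(events: Sequence[Microsaccade], analyzed_duration: float) -> MainSequence:
    """Log-log (displacement, peak velocity) pairs and the mean event rate
    over ``analyzed_duration`` seconds of accepted repeats."""
    if analyzed_duration <= 0:
        raise ValueError("analyzed duration must be positive")
    if len(events) == 0:
        return MainSequence(np.array([]), np.array([]), 0.0)
    disp = np.array([ev.max_displacement for ev in events])
    vel = np.array([ev.peak_velocity for ev in events])
    return MainSequence(
        log_displacement=np.log10(disp),
        log_peak_velocity=np.log10(vel),
        rate=len(events) / analyzed_duration,
    )


def pupil_cv(trace: EyeTrace, window: Tuple[float, float] = (-0.5, 0.75)) -> float:
    """Coefficient of variation (SD/mean) of pupil diameter across time
    within one repeat, ignoring blink samples."""
    m = _window_mask(trace.time, window)
    p = trace.pupil[m]
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("pupil trace is entirely NaN in the analysis window")
    if np.any(p <= 0):
        raise ValueError("pupil diameter must be positive")
    return float(np.std(p) / np.mean(p))


def pupil_cv_subject(traces: Sequence[EyeTrace], window=(-0.5, 0.75)) -> float:
    """Subject-level pupil reactivity: mean per-repeat CV across repeats."""
    cvs = [pupil_cv(tr, window) for tr in traces]
    if not cvs:
        raise ValueError("no analyzable repeats")
    return float(np.mean(cvs))
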