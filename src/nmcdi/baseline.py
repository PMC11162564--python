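"""Slow moving baselines and baseline-crossing peak bounds.

Both the envelope (sEAdi) and airway-pressure baselines are moving 33rd
percentile filters over a centred window, evaluated every ``step_s``
(default 200 ms) and linearly interpolated to the native rate.  The
"variance-amplified" variant raises each anchor by ``variance_gain`` times
the within-window standard deviation, which keeps the baseline above the
noise floor in segments of high baseline variability and makes the
onset/offset crossing detection robust.

Percentile convention: linear interpolation between order statistics
(numpy's ``"linear"`` method).  Windows are clipped to the available
samples at the edges — no padding, so short recordings are never
extrapolated from fabricated data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DetectionError, ParameterError
from .io_session import SignalTrace

__all__ = [
    "BaselineTrace",
    "PeakBounds",
    "moving_percentile_baseline",
    "variance_amplified_baseline",
    "find_baseline_crossings",
]


@dataclass
class BaselineTrace(SignalTrace):
    method: str = "percentile"
    window_s: float = 5.0
    step_s: float = 0.2
    percentile: float = 33.0
    variance_gain: float | None = None


@dataclass
class PeakBounds:
    """Onset/peak/offset times (s) of one peak, located by baseline crossing."""

    onset_time: float
    peak_time: float
    offset_time: float
    onset_clipped: bool = False
    offset_clipped: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_time <= self.peak_time <= self.offset_time):
            raise DataError("PeakBounds must satisfy onset <= peak <= offset")

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


def _anchor_positions(n: int, rate: float, step_s: float) -> np.ndarray:
    step = max(1, int(round(step_s * rate)))
    idx = np.arange(0, n, step)
    if idx[-1] != n - 1:
        idx = np.append(idx, n - 1)
    return idx


def _windowed_anchor_values(
    x: np.ndarray, rate: float, window_s: float, step_s: float, percentile: float,
    variance_gain: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    w = max(1, int(round(window_s * rate)))
    h_lo = w // 2
    h_hi = w - h_lo
    idx = _anchor_positions(n, rate, step_s)
    vals = np.empty(idx.size)
    for k, i in enumerate(idx):
        a = max(0, i - h_lo)
        b = min(n, i + h_hi)
        win = x[a:b]
        v = float(np.percentile(win, percentile, method="linear"))
        if variance_gain is not None:
            v += variance_gain * float(win.std())
        vals[k] = v
    return idx, vals


def moving_percentile_baseline(
    trace: SignalTrace, percentile: float = 33.0, window_s: float = 5.0, step_s: float = 0.2
) -> BaselineTrace:
    """Moving percentile baseline (default: 33rd percentile, 5 s window,
    200 ms step), linearly interpolated between anchors."""
    if trace.duration < window_s:
        raise DataError("moving_percentile_baseline: trace shorter than the window")
    if not (0 <= percentile <= 100):
        raise ParameterError("percentile must be in [0, 100]")
    idx, vals = _windowed_anchor_values(trace.samples, trace.rate, window_s, step_s, percentile, None)
    values = np.interp(np.arange(trace.n), idx, vals)
    return BaselineTrace(
        samples=values, rate=trace.rate, start_time=trace.start_time,
        label=f"baseline({trace.label})", units=trace.units,
        method="percentile", window_s=window_s, step_s=step_s, percentile=percentile,
    )


def variance_amplified_baseline(
    env: SignalTrace, percentile: float = 33.0, window_s: float = 7.5,
    step_s: float = 0.2, variance_gain: float = 0.25,
) -> BaselineTrace:
    """Percentile baseline with each anchor raised by ``variance_gain`` times
    the within-window standard deviation (7.5 s window by default)."""
    if variance_gain < 0:
        raise ParameterError("variance_gain must be >= 0")
    if env.duration < window_s:
        raise DataError("variance_amplified_baseline: trace shorter than the window")
    idx, vals = _windowed_anchor_values(env.samples, env.rate, window_s, step_s, percentile, variance_gain)
    values = np.interp(np.arange(env.n), idx, vals)
    return BaselineTrace(
        samples=values, rate=env.rate, start_time=env.start_time,
        label=f"baseline({env.label})", units=env.units,
        method="percentile_variance_amplified", window_s=window_s, step_s=step_s,
        percentile=percentile, variance_gain=variance_gain,
    )


def scan_crossing_bounds(d: np.ndarray, i_peak: int) -> tuple[int, bool, int, bool]:
    """Indices of the last ``d <= 0`` sample before ``i_peak`` and the first
    after it; trace edges (with a clipped flag) when no crossing exists."""
    if d[i_peak] <= 0:
        raise DetectionError("peak sample is not above the baseline")
    below = d <= 0
    before = np.flatnonzero(below[:i_peak])
    after = np.flatnonzero(below[i_peak + 1 :])
    if before.size:
        i_on, on_clip = int(before[-1]), False
    else:
        i_on, on_clip = 0, True
    if after.size:
        i_off, off_clip = int(i_peak + 1 + after[0]), False
    else:
        i_off, off_clip = d.size - 1, True
    return i_on, on_clip, i_off, off_clip


def find_baseline_crossings(trace: SignalTrace, baseline: BaselineTrace, peak_time: float) -> PeakBounds:
    """Locate the onset/offset of the peak at ``peak_time`` as the nearest
    baseline crossings on either side (trace edges used, and flagged, when
    the signal never returns to the baseline)."""
    if trace.n != baseline.n or abs(trace.rate - baseline.rate) > 1e-9 * trace.rate:
        raise DataError("trace and baseline must share timebase")
    i_peak = trace.index_at(peak_time)
    d = trace.samples - baseline.samples
    i_on, on_clip, i_off, off_clip = scan_crossing_bounds(d, i_peak)
    t = trace.start_time
    return PeakBounds(
        onset_time=t + i_on / trace.rate,
        peak_time=t + i_peak / trace.rate,
        offset_time=t + i_off / trace.rate,
        onset_clipped=on_clip,
        offset_clipped=off_clip,
    )
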