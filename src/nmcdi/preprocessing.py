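"""Raw diaphragm sEMG -> cardiac-artifact-free activity envelope (sEAdi).

The chain is: 20–500 Hz third-order Butterworth bandpass (zero phase),
QRS detection on the ECG lead, 100 ms gating of the EMG around each QRS
complex, and a moving 200 ms RMS envelope.  Gating replaces each gated
window with the sample-wise average of the nearest ungated neighbourhoods
of equal length, which preserves envelope continuity (zeroing the window
would bias the percentile baseline downward).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .errors import DataError, ParameterError, QualityError, UsageError
from .io_session import SignalTrace

__all__ = [
    "QrsEventSeries",
    "EnvelopeTrace",
    "bandpass_filter",
    "detect_qrs",
    "gate_cardiac_artifacts",
    "compute_rms_envelope",
    "preprocess_emg",
]


@dataclass
class QrsEventSeries:
    """Detected QRS complexes: event times (s, strictly increasing) and the
    median inter-beat interval T_HR (s)."""

    event_times: np.ndarray
    median_rr: float

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.size and np.any(np.diff(self.event_times) <= 0):
            raise DataError("QRS event times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.event_times.size)


@dataclass
class EnvelopeTrace(SignalTrace):
    """An sEAdi envelope: a non-negative SignalTrace plus derivation metadata."""

    window_s: float = 0.2
    gate_window_s: float | None = None
    gate_passes: int = 0


def bandpass_filter(
    trace: SignalTrace, low_hz: float = 20.0, high_hz: float = 500.0, order: int = 3
) -> SignalTrace:
    """Zero-phase (forward–backward) Butterworth bandpass."""
    nyq = trace.rate / 2.0
    if not (0 < low_hz < high_hz):
        raise ParameterError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyq:
        raise ParameterError(f"high_hz {high_hz} Hz must be below Nyquist {nyq} Hz")
    sos = scipy.signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=trace.rate, output="sos")
    out = scipy.signal.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=out)


def _moving_median(x: np.ndarray, size: int, decimate: int = 16) -> np.ndarray:
    """Moving median, computed on a decimated copy (the rectified-amplitude
    distribution varies slowly) and linearly interpolated back."""
    idx = np.arange(0, x.size, decimate)
    xd = x[idx]
    wd = max(3, size // decimate)
    med = pd.Series(xd).rolling(wd, center=True, min_periods=1).median().to_numpy()
    return np.interp(np.arange(x.size), idx, med)


def detect_qrs(ecg: SignalTrace, refractory_s: float = 0.2) -> QrsEventSeries:
    """Detect QRS complexes with a rectified-bandpass adaptive threshold.

    The ECG is bandpassed to 5–40 Hz and rectified; peaks must exceed an
    adaptive threshold — the larger of 5x the moving 2 s median and 0.35x
    the moving 2 s maximum of the rectified signal — and be separated by at
    least the refractory period.
    """
    if ecg.duration < 2.0:
        raise DataError("detect_qrs: need at least 2 s of ECG")
    high = min(40.0, 0.45 * ecg.rate)
    filt = bandpass_filter(ecg, 5.0, high, order=2)
    rect = np.abs(filt.samples)
    win = int(round(2.0 * ecg.rate))
    thr = np.maximum(
        5.0 * _moving_median(rect, win),
        0.35 * scipy.ndimage.maximum_filter1d(rect, size=win, mode="nearest"),
    )
    dist = max(1, int(round(refractory_s * ecg.rate)))
    peaks, _ = scipy.signal.find_peaks(rect, height=thr, distance=dist)
    if peaks.size < 3:
        raise QualityError(f"detect_qrs: only {peaks.size} beats found; T_HR undefined")
    times = ecg.start_time + peaks / ecg.rate
    return QrsEventSeries(event_times=times, median_rr=float(np.median(np.diff(times))))


def _gate_mask(n: int, rate: float, start_time: float, events: np.ndarray, window_s: float):
    half = window_s / 2.0
    mask = np.zeros(n, dtype=bool)
    spans = []
    clipped = False
    for t in events:
        i0 = int(np.ceil((t - half - start_time) * rate - 1e-9))
        i1 = int(np.ceil((t + half - start_time) * rate - 1e-9))
        if i1 <= 0 or i0 >= n:
            continue
        if i0 < 0 or i1 > n:
            clipped = True
        i0, i1 = max(i0, 0), min(i1, n)
        mask[i0:i1] = True
        spans.append((i0, i1))
    return mask, spans, clipped


def gate_cardiac_artifacts(
    emg: SignalTrace,
    qrs: QrsEventSeries,
    window_s: float = 0.1,
    passes: int = 1,
    fill: str = "neighbourhood",
) -> SignalTrace:
    """Suppress cardiac crosstalk by gating 100 ms windows around each QRS.

    ``fill`` chooses the replacement for gated samples:

    * ``"neighbourhood"`` (default): sample-wise average of the nearest
      preceding and following ungated segments of equal length;
    * ``"hold"``: last ungated value;
    * ``"zero"``: zeros.

    With ``passes=2`` a second QRS detection is run on the once-gated
    signal and its events gated too — this removes a secondary peak family
    (bundle branch block, paced rhythm) at a different latency.
    """
    if fill not in ("neighbourhood", "hold", "zero"):
        raise UsageError(f"unknown gate fill {fill!r}")
    if passes not in (1, 2):
        raise UsageError("passes must be 1 or 2")

    x = emg.samples.copy()
    mask, spans, clipped = _gate_mask(emg.n, emg.rate, emg.start_time, qrs.event_times, window_s)
    ungated_idx = np.flatnonzero(~mask)
    if spans and ungated_idx.size == 0:
        raise QualityError("gating would remove the entire trace")
    for i0, i1 in spans:
        length = i1 - i0
        if fill == "zero":
            x[i0:i1] = 0.0
            continue
        pos_left = np.searchsorted(ungated_idx, i0)  # ungated indices strictly before gate
        pos_right = np.searchsorted(ungated_idx, i1)
        if fill == "hold":
            src = ungated_idx[pos_left - 1] if pos_left > 0 else (
                ungated_idx[pos_right] if pos_right < ungated_idx.size else None
            )
            x[i0:i1] = emg.samples[src] if src is not None else 0.0
            continue
        left = ungated_idx[max(0, pos_left - length) : pos_left]
        right = ungated_idx[pos_right : pos_right + length]
        segs = []
        if left.size == length:
            segs.append(emg.samples[left])
        if right.size == length:
            segs.append(emg.samples[right])
        if not segs:
            # very short trace: fall back on whatever neighbours exist
            both = np.concatenate([emg.samples[left], emg.samples[right]])
            x[i0:i1] = float(np.mean(both)) if both.size else 0.0
            clipped = True
            continue
        x[i0:i1] = np.mean(segs, axis=0)

    out = replace(emg, samples=x, meta={**emg.meta, "gated_events": len(spans), "gate_clipped": clipped})
    if passes == 2:
        try:
            qrs2 = detect_qrs(out)
        except QualityError:
            return out  # no secondary peak family to remove
        out = gate_cardiac_artifacts(out, qrs2, window_s=window_s, passes=1, fill=fill)
        out.meta["gate_passes"] = 2
    return out


def compute_rms_envelope(emg: SignalTrace, window_s: float = 0.2) -> EnvelopeTrace:
    """Centred moving RMS envelope (window truncated at the trace edges)."""
    if emg.duration <= window_s:
        raise DataError("compute_rms_envelope: trace shorter than the RMS window")
    w = max(1, int(round(window_s * emg.rate)))
    h_lo = w // 2
    h_hi = w - h_lo  # half-open window [i - h_lo, i + h_hi)
    sq = emg.samples.astype(float) ** 2
    cs = np.concatenate([[0.0], np.cumsum(sq)])
    n = emg.n
    i = np.arange(n)
    a = np.clip(i - h_lo, 0, n)
    b = np.clip(i + h_hi, 0, n)
    mean_sq = (cs[b] - cs[a]) / (b - a)
    env = np.sqrt(np.maximum(mean_sq, 0.0))
    return EnvelopeTrace(
        samples=env,
        rate=emg.rate,
        start_time=emg.start_time,
        label="sEAdi",
        units=emg.units,
        meta=dict(emg.meta),
        window_s=window_s,
        gate_window_s=emg.meta.get("gate_window_s"),
        gate_passes=emg.meta.get("gate_passes", 1 if emg.meta.get("gated_events") else 0),
    )


def preprocess_emg(
    emg: SignalTrace,
    ecg: SignalTrace,
    low_hz: float = 20.0,
    high_hz: float = 500.0,
    order: int = 3,
    gate_window_s: float = 0.1,
    gate_passes: int = 1,
    gate_fill: str = "neighbourhood",
    rms_window_s: float = 0.2,
) -> tuple[EnvelopeTrace, QrsEventSeries]:
    """Full chain: bandpass -> QRS detection -> gating -> RMS envelope."""
    filtered = bandpass_filter(emg, low_hz, high_hz, order)
    qrs = detect_qrs(ecg)
    gated = gate_cardiac_artifacts(filtered, qrs, window_s=gate_window_s, passes=gate_passes, fill=gate_fill)
    gated.meta["gate_window_s"] = gate_window_s
    env = compute_rms_envelope(gated, window_s=rms_window_s)
    return env, qrs
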