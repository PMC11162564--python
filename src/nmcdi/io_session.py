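"""Signal containers, delimited channel-table I/O and session alignment.

Conventions used throughout the package:

* sample ``i`` of a trace sits at ``start_time + i / rate`` (seconds);
* all windows are half-open ``[t0, t0 + w)`` in seconds;
* channels keep their native rate (EMG typically 2048 Hz, ventilator
  100 Hz); cross-channel comparisons are done in seconds, never by
  sample index.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, UsageError

__all__ = [
    "SignalTrace",
    "RecordingSession",
    "ChannelTableDialect",
    "read_channel_table",
    "write_channel_table",
    "align_session",
]


@dataclass
class SignalTrace:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    samples : array-like
        Finite real values; length > 0.
    rate : float
        Sampling rate in Hz (> 0), constant over the trace.
    start_time : float
        Time of sample 0, in seconds.
    label, units : str
        Channel name and physical units (e.g. ``"uV"``, ``"cmH2O"``).
    """

    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    label: str = ""
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise DataError(f"trace {self.label!r}: need a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise DataError(f"trace {self.label!r}: samples must be finite")
        if not (self.rate > 0 and np.isfinite(self.rate)):
            raise DataError(f"trace {self.label!r}: rate must be positive, got {self.rate}")

    # -- time geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def end_time(self) -> float:
        """End of the half-open span covered by the trace."""
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate

    def index_at(self, t: float, clip: bool = True) -> int:
        """Index of the sample nearest to time ``t``."""
        i = int(round((t - self.start_time) * self.rate))
        if clip:
            return min(max(i, 0), self.n - 1)
        if not (0 <= i < self.n):
            raise DataError(f"time {t} s outside trace span")
        return i

    def value_at(self, t: float) -> float:
        return float(self.samples[self.index_at(t)])

    def crop(self, t0: float, t1: float) -> "SignalTrace":
        """Return the sub-trace covering ``[t0, t1)``."""
        if t1 <= t0:
            raise DataError("crop: empty interval")
        i0 = max(0, int(np.ceil((t0 - self.start_time) * self.rate - 1e-9)))
        i1 = min(self.n, int(np.ceil((t1 - self.start_time) * self.rate - 1e-9)))
        if i1 <= i0:
            raise DataError("crop: no samples in interval")
        return replace(
            self,
            samples=self.samples[i0:i1].copy(),
            start_time=self.start_time + i0 / self.rate,
        )


@dataclass
class RecordingSession:
    """Aligned multichannel recording plus the PEEP schedule.

    ``peep_schedule`` is a list of ``(start_time_s, peep_cmH2O)`` pairs with
    strictly increasing start times; each level runs until the next start
    (the last one until the end of the pressure trace).
    """

    emg_di: SignalTrace
    ecg: SignalTrace
    paw: SignalTrace
    flow: Optional[SignalTrace] = None
    volume: Optional[SignalTrace] = None
    peep_schedule: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.peep_schedule]
        peeps = [p for _, p in self.peep_schedule]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise DataError("peep_schedule start times must be strictly increasing")
        if any(p < 0 for p in peeps):
            raise DataError("peep values must be >= 0 cmH2O")

    def traces(self) -> list:
        out = [self.emg_di, self.ecg, self.paw]
        if self.flow is not None:
            out.append(self.flow)
        if self.volume is not None:
            out.append(self.volume)
        return out

    def level_intervals(self) -> list:
        """``(start_s, end_s, peep_cmH2O)`` per PEEP level, clipped to the
        pressure trace span."""
        out = []
        for k, (t0, peep) in enumerate(self.peep_schedule):
            t1 = (
                self.peep_schedule[k + 1][0]
                if k + 1 < len(self.peep_schedule)
                else self.paw.end_time
            )
            t0 = max(t0, self.paw.start_time)
            t1 = min(t1, self.paw.end_time)
            if t1 > t0:
                out.append((t0, t1, peep))
        return out


@dataclass
class ChannelTableDialect:
    """How a delimited channel table is laid out.

    ``channel_columns`` maps column name -> role/label (e.g.
    ``{"emg": "emg_di", "ecg": "ecg"}``); ``units`` optionally maps the
    same column names to physical units.
    """

    delimiter: str = ","
    time_column: str = "time_s"
    channel_columns: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)


_MAX_JITTER_FRAC = 0.01  # tolerated deviation of any time step from the median


def read_channel_table(path, dialect: ChannelTableDialect) -> list:
    """Read one delimited table into one :class:`SignalTrace` per channel.

    The sampling rate is inferred as ``1 / median(diff(time))``; sampling
    that deviates from uniform by more than 1% of the nominal step is
    rejected as non-uniform.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"channel table not found: {path}")
    df = pd.read_csv(path, sep=dialect.delimiter)
    missing = [c for c in [dialect.time_column, *dialect.channel_columns] if c not in df.columns]
    if missing:
        raise ConfigError(f"missing columns {missing} in {path} (found {list(df.columns)})")
    t = df[dialect.time_column].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path}: time column must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > _MAX_JITTER_FRAC * step:
        raise DataError(
            f"{path}: non-uniform sampling (jitter beyond {_MAX_JITTER_FRAC:.0%} of the median step)"
        )
    rate = 1.0 / step
    traces = []
    for col, role in dialect.channel_columns.items():
        traces.append(
            SignalTrace(
                samples=df[col].to_numpy(dtype=float),
                rate=rate,
                start_time=float(t[0]),
                label=role,
                units=dialect.units.get(col, ""),
            )
        )
    return traces


def write_channel_table(traces: Sequence[SignalTrace], path, dialect: ChannelTableDialect) -> None:
    """Write traces sharing one rate and span as a delimited table.

    Values are written with 17 significant digits so that a read/write
    round trip preserves float64 samples.
    """
    traces = list(traces)
    if not traces:
        raise UsageError("write_channel_table: empty trace list")
    rate = traces[0].rate
    n = traces[0].n
    t0 = traces[0].start_time
    for tr in traces[1:]:
        if abs(tr.rate - rate) > 1e-9 * rate or tr.n != n or abs(tr.start_time - t0) > 1e-9:
            raise UsageError("write_channel_table: traces must share rate, length and start (resample first)")
    cols = {dialect.time_column: traces[0].times()}
    names = list(dialect.channel_columns) if dialect.channel_columns else [tr.label or f"ch{k}" for k, tr in enumerate(traces)]
    if len(names) != len(traces):
        raise UsageError("dialect channel_columns does not match the number of traces")
    for name, tr in zip(names, traces):
        cols[name] = tr.samples
    pd.DataFrame(cols).to_csv(path, sep=dialect.delimiter, index=False, float_format="%.17g")


def align_session(
    emg: SignalTrace,
    ecg: SignalTrace,
    paw: SignalTrace,
    flow: Optional[SignalTrace] = None,
    volume: Optional[SignalTrace] = None,
    peep_schedule: Optional[list] = None,
) -> RecordingSession:
    """Crop all channels to their common time span (native rates kept)."""
    present = [tr for tr in (emg, ecg, paw, flow, volume) if tr is not None]
    t0 = max(tr.start_time for tr in present)
    t1 = min(tr.end_time for tr in present)
    if t1 <= t0:
        raise DataError("align_session: channels have no temporal overlap")

    def _crop(tr):
        if tr is None:
            return None
        if tr.start_time >= t0 - 1e-12 and tr.end_time <= t1 + 1e-12:
            return tr
        return tr.crop(t0, t1)

    return RecordingSession(
        emg_di=_crop(emg),
        ecg=_crop(ecg),
        paw=_crop(paw),
        flow=_crop(flow),
        volume=_crop(volume),
        peep_schedule=list(peep_schedule or []),
    )
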