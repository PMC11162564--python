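"""Occlusion-manoeuvre detection and time-product computation.

An end-expiratory occlusion manoeuvre (Pocc) appears in airway pressure as
a negative deflection relative to the set PEEP.  Each detected event gets:

* ``ptp_occ`` — pressure–time product, the area between the moving Paw
  baseline and the Pocc waveform over the onset–offset bounds (cmH2O*s);
* morphology — maximum downward/upward slope and their ratio
  (``release_ratio``), used to flag abrupt or irregular effort cessation;
* a matched sEAdi envelope peak with ``etp_di`` (electrical–time product),
  ``aub`` (area under the moving baseline) and ``auc_tot`` (total area),
  which satisfy ``auc_tot = etp_di + aub`` by construction.

Integrals use the trapezoidal rule at the channel's native rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage

from .baseline import BaselineTrace, PeakBounds, find_baseline_crossings, scan_crossing_bounds
from .errors import DataError, QualityError
from .io_session import SignalTrace
from .preprocessing import EnvelopeTrace

__all__ = [
    "PoccMorphology",
    "PoccEvent",
    "SEAdiPeak",
    "ManoeuvreRecord",
    "detect_occlusions",
    "select_first_breath",
    "compute_ptp",
    "match_seadi_peak",
    "compute_etp",
    "compute_pocc_morphology",
]


@dataclass
class PoccMorphology:
    max_down_slope: float  # cmH2O/s, > 0
    max_up_slope: float    # cmH2O/s, > 0
    release_ratio: float   # up/down; >> 1 flags abrupt release


@dataclass
class PoccEvent:
    bounds: PeakBounds
    trough_time: float
    trough_depth: float      # cmH2O below set PEEP
    set_peep: float
    ptp_occ: Optional[float] = None
    morphology: Optional[PoccMorphology] = None
    valid: bool = True
    invalid_reason: str = ""


@dataclass
class SEAdiPeak:
    bounds: PeakBounds
    peak_value: float        # uV
    baseline_at_peak: float  # uV
    etp_di: Optional[float] = None
    aub: Optional[float] = None
    auc_tot: Optional[float] = None
    tdi_ratio: Optional[float] = None      # % of T_HR; None = unevaluable
    snr_pct: Optional[float] = None        # % of baseline
    bell_error_pct: Optional[float] = None # % of auc_tot


@dataclass
class ManoeuvreRecord:
    pocc: PoccEvent
    seadi: Optional[SEAdiPeak]
    peep_level: float
    trial_id: str = ""
    verdicts: dict = field(default_factory=dict)


def detect_occlusions(
    paw: SignalTrace,
    set_peep: float,
    min_depth: float = 2.0,
    min_duration_s: float = 0.2,
    paw_baseline: Optional[BaselineTrace] = None,
) -> list:
    """Detect occlusion manoeuvres as maximal intervals with
    ``paw < set_peep - min_depth`` lasting at least ``min_duration_s``.

    Each interval is reduced to its trough plus baseline-crossing bounds
    against the moving Paw baseline.  Events sorted by time; intervals that
    collapse onto the same crossing bounds are merged (deepest trough kept).
    """
    from .baseline import moving_percentile_baseline

    if paw_baseline is None:
        paw_baseline = moving_percentile_baseline(paw)
    if paw_baseline.n != paw.n:
        raise DataError("paw baseline must share the pressure timebase")

    below = paw.samples < (set_peep - min_depth)
    if not np.any(below):
        return []
    edges = np.diff(below.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(paw.n)
    min_len = min_duration_s * paw.rate
    deflection = paw_baseline.samples - paw.samples  # > 0 inside a dip

    events: dict = {}
    for i0, i1 in zip(starts, ends):
        if i1 - i0 < min_len:
            continue
        i_trough = i0 + int(np.argmin(paw.samples[i0:i1]))
        if deflection[i_trough] <= 0:
            continue
        i_on, on_clip, i_off, off_clip = scan_crossing_bounds(deflection, i_trough)
        key = (i_on, i_off)
        depth = float(set_peep - paw.samples[i_trough])
        if key in events and events[key].trough_depth >= depth:
            continue
        t0 = paw.start_time
        events[key] = PoccEvent(
            bounds=PeakBounds(
                onset_time=t0 + i_on / paw.rate,
                peak_time=t0 + i_trough / paw.rate,
                offset_time=t0 + i_off / paw.rate,
                onset_clipped=on_clip,
                offset_clipped=off_clip,
            ),
            trough_time=t0 + i_trough / paw.rate,
            trough_depth=depth,
            set_peep=set_peep,
        )
    return sorted(events.values(), key=lambda e: e.trough_time)


def select_first_breath(events: Sequence[PoccEvent], occlusion_windows: Sequence[tuple]) -> list:
    """Keep only the earliest event (by onset) within each occlusion window.

    Events outside every window are dropped: the windows define where the
    airway was actually occluded.
    """
    kept = []
    for w0, w1 in occlusion_windows:
        inside = [e for e in events if w0 <= e.trough_time < w1]
        if inside:
            kept.append(min(inside, key=lambda e: e.bounds.onset_time))
    return sorted(kept, key=lambda e: e.trough_time)


def _trapz_between(y: np.ndarray, rate: float, i0: int, i1: int) -> float:
    return float(np.trapezoid(y[i0 : i1 + 1], dx=1.0 / rate))


def compute_ptp(paw: SignalTrace, paw_baseline: BaselineTrace, event: PoccEvent) -> PoccEvent:
    """Fill ``ptp_occ`` = integral of max(baseline - paw, 0) over the bounds."""
    i0 = paw.index_at(event.bounds.onset_time)
    i1 = paw.index_at(event.bounds.offset_time)
    area = _trapz_between(np.maximum(paw_baseline.samples - paw.samples, 0.0), paw.rate, i0, i1)
    ev = replace(event, ptp_occ=area)
    if area <= 0:
        ev.valid = False
        ev.invalid_reason = "non-positive pressure-time product"
    return ev


def match_seadi_peak(
    env: EnvelopeTrace,
    env_baseline: BaselineTrace,
    event: PoccEvent,
    search_pad_s: float = 0.5,
) -> SEAdiPeak:
    """Find the sEAdi envelope peak belonging to one occlusion: the argmax of
    envelope minus baseline within the occlusion bounds padded by
    ``search_pad_s`` (electromechanical delay allowance)."""
    t0 = max(env.start_time, event.bounds.onset_time - search_pad_s)
    t1 = min(env.end_time - 1.0 / env.rate, event.bounds.offset_time + search_pad_s)
    i0, i1 = env.index_at(t0), env.index_at(t1)
    if i1 <= i0:
        raise QualityError("match_seadi_peak: empty search window")
    d = env.samples[i0 : i1 + 1] - env_baseline.samples[i0 : i1 + 1]
    if np.max(d) <= 0:
        raise QualityError("no sEAdi sample above baseline near the occlusion")
    i_peak = i0 + int(np.argmax(d))
    t_peak = env.start_time + i_peak / env.rate
    bounds = find_baseline_crossings(env, env_baseline, t_peak)
    return SEAdiPeak(
        bounds=bounds,
        peak_value=float(env.samples[i_peak]),
        baseline_at_peak=float(env_baseline.samples[i_peak]),
    )


def compute_etp(env: EnvelopeTrace, env_baseline: BaselineTrace, peak: SEAdiPeak) -> SEAdiPeak:
    """Fill ``etp_di``, ``aub`` and ``auc_tot`` over the peak bounds.

    ``max(env - b, 0) + min(env, b) == env`` pointwise, so the identity
    ``auc_tot = etp_di + aub`` holds to rounding; asserted at 1e-9 relative.
    """
    i0 = env.index_at(peak.bounds.onset_time)
    i1 = env.index_at(peak.bounds.offset_time)
    e = env.samples
    b = env_baseline.samples
    etp = _trapz_between(np.maximum(e - b, 0.0), env.rate, i0, i1)
    aub = _trapz_between(np.minimum(e, b), env.rate, i0, i1)
    auc = _trapz_between(e, env.rate, i0, i1)
    if auc > 0 and abs(auc - (etp + aub)) > 1e-9 * auc:
        raise AssertionError("area identity auc_tot = etp_di + aub violated")
    return replace(peak, etp_di=etp, aub=aub, auc_tot=auc)


def compute_pocc_morphology(
    paw: SignalTrace, paw_baseline: BaselineTrace, event: PoccEvent
) -> PoccEvent:
    """Fill release morphology: max downward slope before the trough, max
    upward slope after it, and their ratio.  Derivative by centred
    differences after 3-sample median smoothing at the ventilator rate.
    Degenerate events (trough at a bound) are marked unevaluable."""
    i0 = paw.index_at(event.bounds.onset_time)
    i1 = paw.index_at(event.bounds.offset_time)
    it = paw.index_at(event.trough_time)
    if it <= i0 or it >= i1 or i1 - i0 < 3:
        ev = replace(event, morphology=None)
        ev.valid = False
        ev.invalid_reason = "degenerate occlusion morphology (trough at bound)"
        return ev
    # edge-replicating median: a release step at the segment edge must
    # survive the smoothing
    seg = scipy.ndimage.median_filter(paw.samples[i0 : i1 + 1], size=3, mode="nearest")
    d = np.gradient(seg) * paw.rate
    jt = it - i0
    max_down = float(np.max(-d[: jt + 1]))
    max_up = float(np.max(d[jt:]))
    if max_down <= 0 or max_up <= 0:
        ev = replace(event, morphology=None)
        ev.valid = False
        ev.invalid_reason = "degenerate occlusion morphology (no slope)"
        return ev
    return replace(
        event,
        morphology=PoccMorphology(
            max_down_slope=max_down,
            max_up_slope=max_up,
            release_ratio=max_up / max_down,
        ),
    )
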