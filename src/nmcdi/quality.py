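"""Automated waveform quality criteria.

Each manoeuvre is screened on five criteria before entering the coupling
analysis:

* **pocc morphology** — abrupt/irregular cessation of the inspiratory
  effort, operationalised as the release ratio (max upward / max downward
  Paw slope) exceeding a threshold;
* **snr** — envelope peak value relative to the moving baseline (%);
* **tdi** — median interval between envelope peaks relative to the median
  heart inter-beat interval (%); near 100% flags cardiac contamination;
* **aub** — area under the moving baseline as % of the total area under
  the envelope within the peak bounds;
* **bell morphology** — integrated absolute residual of the best-fit
  Gaussian bell as % of the total area.

Two built-in automated profiles, ``tolerant`` and ``strict``, plus a
``manual`` profile that applies no automated criterion.  All comparisons
are strict inequalities: a value exactly at a cut-off is kept.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.signal

from .baseline import BaselineTrace
from .errors import QualityError
from .events import ManoeuvreRecord, SEAdiPeak
from .preprocessing import EnvelopeTrace, QrsEventSeries

__all__ = [
    "QualityProfile",
    "QualityVerdict",
    "builtin_profiles",
    "compute_snr_pct",
    "compute_tdi_ratio",
    "compute_bell_error_pct",
    "apply_profile",
    "summarise_exclusions",
    "CRITERIA",
]

CRITERIA = ("pocc_morphology", "snr", "tdi", "aub", "bell_morphology")


@dataclass(frozen=True)
class QualityProfile:
    """Named set of exclusion cut-offs.  ``None`` disables a criterion."""

    name: str
    tdi_max_pct: Optional[float] = None        # exclude if tdi_ratio < this
    snr_min_pct: Optional[float] = None        # exclude if snr_pct < this
    aub_max_pct: Optional[float] = None        # exclude if aub fraction > this
    bell_error_max_pct: Optional[float] = None # exclude if bell error > this
    pocc_release_ratio_max: Optional[float] = None  # exclude if ratio > this

    @property
    def automated(self) -> bool:
        return any(
            v is not None
            for v in (self.tdi_max_pct, self.snr_min_pct, self.aub_max_pct,
                      self.bell_error_max_pct, self.pocc_release_ratio_max)
        )


@dataclass
class QualityVerdict:
    included: bool
    failed_criteria: frozenset
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.included == (len(self.failed_criteria) == 0)


def builtin_profiles() -> dict:
    """The manual / tolerant / strict profiles.

    Tolerant excludes at Tdi < 110% of T_HR, SNR < 140% of baseline,
    AUB > 40% of AUC_tot, bell error > 30%; strict tightens SNR to < 175%,
    AUB to > 30% and bell error to > 25%.  The release-ratio threshold
    (2.0) applies to both automated profiles.
    """
    return {
        "manual": QualityProfile(name="manual"),
        "tolerant": QualityProfile(
            name="tolerant", tdi_max_pct=110.0, snr_min_pct=140.0,
            aub_max_pct=40.0, bell_error_max_pct=30.0, pocc_release_ratio_max=2.0,
        ),
        "strict": QualityProfile(
            name="strict", tdi_max_pct=110.0, snr_min_pct=175.0,
            aub_max_pct=30.0, bell_error_max_pct=25.0, pocc_release_ratio_max=2.0,
        ),
    }


def compute_snr_pct(peak: SEAdiPeak) -> float:
    """Envelope peak value as % of the moving baseline at the peak."""
    if peak.baseline_at_peak <= 0:
        raise QualityError("SNR undefined: baseline at peak is not positive")
    return 100.0 * peak.peak_value / peak.baseline_at_peak


def compute_tdi_ratio(
    env: EnvelopeTrace,
    env_baseline: BaselineTrace,
    qrs: QrsEventSeries,
    window_s: float = 15.0,
    centred_on: float = 0.0,
    min_peak_distance_s: float = 0.25,
    rel_height: float = 0.2,
) -> Optional[float]:
    """Median sEAdi interpeak interval (Tdi) as % of the median heart
    inter-beat interval (T_HR), over a window centred on the manoeuvre.

    Peaks are local envelope maxima above the baseline whose *prominence*
    reaches ``rel_height`` of the largest excess in the window — small
    wiggles riding on one burst are not separate peaks, while distinct
    cardiac-locked bursts keep their full prominence.  Returns ``None``
    (criterion unevaluable) with fewer than 3 peaks.
    """
    i0 = env.index_at(centred_on - window_s / 2)
    i1 = env.index_at(centred_on + window_s / 2)
    d = env.samples[i0 : i1 + 1] - env_baseline.samples[i0 : i1 + 1]
    if d.size < 3 or np.max(d) <= 0:
        return None
    prom = rel_height * float(np.max(d))
    dist = max(1, int(round(min_peak_distance_s * env.rate)))
    peaks, _ = scipy.signal.find_peaks(d, height=0.0, prominence=prom, distance=dist)
    if peaks.size < 3:
        return None
    tdi = float(np.median(np.diff(peaks))) / env.rate
    return 100.0 * tdi / qrs.median_rr


def _gauss(t: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def compute_bell_error_pct(
    env: EnvelopeTrace, env_baseline: BaselineTrace, peak: SEAdiPeak
) -> float:
    """Deviation of the sEAdi peak from a bell shape.

    A Gaussian ``a*exp(-(t-mu)^2/(2 sigma^2))`` riding on the moving
    baseline is fitted by multi-start least squares over the peak bounds;
    the error is the integrated absolute residual as % of ``auc_tot``.
    Returns 100 (maximal error) if every start fails.
    """
    if peak.auc_tot is None or peak.auc_tot <= 0:
        raise QualityError("bell error needs auc_tot > 0 (run compute_etp first)")
    i0 = env.index_at(peak.bounds.onset_time)
    i1 = env.index_at(peak.bounds.offset_time)
    t = env.start_time + np.arange(i0, i1 + 1) / env.rate
    y = env.samples[i0 : i1 + 1] - env_baseline.samples[i0 : i1 + 1]
    span = max(peak.bounds.duration, 2.0 / env.rate)
    a0 = max(peak.peak_value - peak.baseline_at_peak, 1e-12)
    lo = [1e-12, peak.bounds.onset_time, span / 50.0]
    hi = [10.0 * a0 + 1e-9, peak.bounds.offset_time, 2.0 * span]
    starts = [
        (a0, peak.bounds.peak_time, span / 4.0),
        (a0, peak.bounds.peak_time, span / 8.0),
        (0.6 * a0, (peak.bounds.onset_time + peak.bounds.offset_time) / 2.0, span / 3.0),
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = scipy.optimize.least_squares(
                lambda p: _gauss(t, *p) - y, x0, bounds=(lo, hi), method="trf", max_nfev=200
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return 100.0
    resid = np.abs(y - _gauss(t, *best.x))
    err = float(np.trapezoid(resid, dx=1.0 / env.rate))
    return 100.0 * err / peak.auc_tot


def apply_profile(record: ManoeuvreRecord, profile: QualityProfile) -> QualityVerdict:
    """Evaluate one manoeuvre against a profile.

    Policy for unevaluable criteria: missing Pocc morphology excludes
    (conservative — the release shape could not be verified); missing Tdi
    does not (it needs several peaks, which clean slow breathing may not
    provide in the window).
    """
    pocc, peak = record.pocc, record.seadi
    metrics = {
        "release_ratio": pocc.morphology.release_ratio if pocc.morphology else None,
        "snr_pct": peak.snr_pct if peak else None,
        "tdi_ratio": peak.tdi_ratio if peak else None,
        "aub_pct": (100.0 * peak.aub / peak.auc_tot)
        if peak and peak.aub is not None and peak.auc_tot
        else None,
        "bell_error_pct": peak.bell_error_pct if peak else None,
    }
    failed = set()
    if profile.automated:
        if profile.pocc_release_ratio_max is not None:
            rr = metrics["release_ratio"]
            if rr is None or rr > profile.pocc_release_ratio_max:
                failed.add("pocc_morphology")
        if profile.snr_min_pct is not None:
            s = metrics["snr_pct"]
            if s is None or s < profile.snr_min_pct:
                failed.add("snr")
        if profile.tdi_max_pct is not None:
            td = metrics["tdi_ratio"]
            if td is not None and td < profile.tdi_max_pct:
                failed.add("tdi")
        if profile.aub_max_pct is not None:
            ab = metrics["aub_pct"]
            if ab is None or ab > profile.aub_max_pct:
                failed.add("aub")
        if profile.bell_error_max_pct is not None:
            be = metrics["bell_error_pct"]
            if be is None or be > profile.bell_error_max_pct:
                failed.add("bell_morphology")
    return QualityVerdict(included=not failed, failed_criteria=frozenset(failed), metrics=metrics)


def summarise_exclusions(records: Sequence[ManoeuvreRecord], profile_name: str) -> pd.DataFrame:
    """Per-criterion exclusion counts and fractions under one profile.

    A manoeuvre failing several criteria is counted under each of them
    (fractions are over all manoeuvres and need not sum to 1).
    """
    n = len(records)
    rows = []
    included = 0
    counts = {c: 0 for c in CRITERIA}
    for r in records:
        v = r.verdicts.get(profile_name)
        if v is None:
            continue
        if v.included:
            included += 1
        for c in v.failed_criteria:
            counts[c] += 1
    rows.append({"criterion": "included", "count": included, "fraction": included / n if n else np.nan})
    for c in CRITERIA:
        rows.append({"criterion": c, "count": counts[c], "fraction": counts[c] / n if n else np.nan})
    return pd.DataFrame(rows)
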