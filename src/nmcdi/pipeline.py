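"""End-to-end orchestration: session -> manoeuvre records -> trial summary.

Deterministic given (session, config): every stage is a pure function of
its inputs.  The run log records the effective configuration, package
version and per-stage counts so a run can be reproduced exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import CovSummary, PeepTrialResult, compute_cov, normalise_trial
from .baseline import moving_percentile_baseline, variance_amplified_baseline
from .config import RunConfig
from .errors import QualityError
from .events import (
    ManoeuvreRecord,
    compute_etp,
    compute_pocc_morphology,
    compute_ptp,
    detect_occlusions,
    match_seadi_peak,
    select_first_breath,
)
from .io_session import RecordingSession
from .preprocessing import preprocess_emg
from .quality import apply_profile, builtin_profiles, compute_bell_error_pct, compute_snr_pct, compute_tdi_ratio, summarise_exclusions

__all__ = ["PipelineResult", "run_pipeline", "records_table"]


@dataclass
class PipelineResult:
    records: list
    trial: Optional[PeepTrialResult]
    cov: Optional[CovSummary]
    exclusion_summary: pd.DataFrame
    run_log: dict = field(default_factory=dict)


def _cluster_windows(events, gap_s: float):
    """Derive occlusion windows by clustering events separated by < gap_s."""
    windows = []
    for e in events:
        t0, t1 = e.bounds.onset_time, e.bounds.offset_time
        if windows and t0 - windows[-1][1] < gap_s:
            windows[-1] = (windows[-1][0], max(windows[-1][1], t1))
        else:
            windows.append((t0, t1))
    # widen slightly so trough times of merged events stay inside
    return [(a - 1e-6, b + 1e-6) for a, b in windows]


def run_pipeline(session: RecordingSession, config: Optional[RunConfig] = None) -> PipelineResult:
    """Run preprocessing, event detection, quality screening and trial
    analysis on one recording session."""
    cfg = config or RunConfig()
    pp, bl, ev, qc = cfg.preprocessing, cfg.baseline, cfg.events, cfg.quality

    env, qrs = preprocess_emg(
        session.emg_di, session.ecg,
        low_hz=pp.low_hz, high_hz=pp.high_hz, order=pp.order,
        gate_window_s=pp.gate_window_s, gate_passes=pp.gate_passes,
        gate_fill=pp.gate_fill, rms_window_s=pp.rms_window_s,
    )
    env_base = variance_amplified_baseline(
        env, percentile=bl.percentile, window_s=bl.advanced_window_s,
        step_s=bl.step_s, variance_gain=bl.variance_gain,
    )
    paw_base = moving_percentile_baseline(
        session.paw, percentile=bl.percentile, window_s=bl.basic_window_s, step_s=bl.step_s,
    )

    profiles = builtin_profiles()
    profiles[cfg.quality.profile] = cfg.resolved_profile()

    records = []
    skipped = []
    levels = session.level_intervals()
    for t0, t1, peep in levels:
        seg0 = t0 + (ev.level_settle_s if t0 > session.paw.start_time else 0.0)
        if t1 - seg0 <= 1.0 / session.paw.rate:
            continue
        paw_seg = session.paw.crop(seg0, t1)
        base_seg = paw_base.crop(seg0, t1)
        found = detect_occlusions(
            paw_seg, set_peep=peep, min_depth=ev.min_depth_cmh2o,
            min_duration_s=ev.min_duration_s, paw_baseline=base_seg,
        )
        meta_windows = session.meta.get("occlusion_windows")
        if ev.use_meta_windows and meta_windows is not None:
            windows = [(a, b) for a, b in meta_windows if seg0 <= a < t1]
        else:
            windows = _cluster_windows(found, ev.window_gap_s)
        found = select_first_breath(found, windows)
        for event in found:
            event = compute_ptp(paw_seg, base_seg, event)
            event = compute_pocc_morphology(paw_seg, base_seg, event)
            if event.ptp_occ is None or event.ptp_occ <= 0:
                skipped.append((event.trough_time, "invalid ptp"))
                continue
            try:
                peak = match_seadi_peak(env, env_base, event, search_pad_s=ev.search_pad_s)
            except QualityError as exc:
                skipped.append((event.trough_time, str(exc)))
                continue
            peak = compute_etp(env, env_base, peak)
            try:
                peak.snr_pct = compute_snr_pct(peak)
            except QualityError:
                peak.snr_pct = None
            peak.tdi_ratio = compute_tdi_ratio(
                env, env_base, qrs, window_s=qc.tdi_window_s,
                centred_on=peak.bounds.peak_time,
                min_peak_distance_s=qc.tdi_min_peak_distance_s,
                rel_height=qc.tdi_rel_height,
            )
            peak.bell_error_pct = compute_bell_error_pct(env, env_base, peak)
            record = ManoeuvreRecord(pocc=event, seadi=peak, peep_level=peep, trial_id=cfg.trial_id)
            for name, prof in profiles.items():
                record.verdicts[name] = apply_profile(record, prof)
            records.append(record)

    active = cfg.quality.profile
    included = [r for r in records if r.verdicts[active].included]
    trial = None
    trial_reason = ""
    try:
        trial = normalise_trial(
            included, reference_peep=cfg.analysis.reference_peep,
            trial_id=cfg.trial_id, expected_levels=[p for _, _, p in levels],
        )
    except QualityError as exc:
        trial_reason = str(exc)

    cov = None
    cov_reason = ""
    if trial is not None:
        groups = [vals for vals in ([v[2] for v in g] for g in trial.per_level.values())]
        try:
            cov = compute_cov(groups)
        except Exception as exc:
            cov_reason = str(exc)

    run_log = {
        "version": __version__,
        "config": cfg.model_dump(),
        "profile": active,
        "n_levels": len(levels),
        "n_manoeuvres": len(records),
        "n_included": len(included),
        "n_skipped": len(skipped),
        "skipped": [{"time_s": round(t, 3), "reason": r} for t, r in skipped],
        "trial_complete": bool(trial.complete) if trial else False,
        "trial_unusable_reason": trial_reason,
        "cov_unavailable_reason": cov_reason,
        "median_rr_s": qrs.median_rr,
    }
    return PipelineResult(
        records=records,
        trial=trial,
        cov=cov,
        exclusion_summary=summarise_exclusions(records, active),
        run_log=run_log,
    )


def records_table(records) -> pd.DataFrame:
    """One row per manoeuvre with all derived metrics and per-profile verdicts."""
    rows = []
    for k, r in enumerate(records):
        p, s = r.pocc, r.seadi
        row = {
            "manoeuvre": k,
            "trial_id": r.trial_id,
            "peep_cmh2o": r.peep_level,
            "trough_time_s": p.trough_time,
            "trough_depth_cmh2o": p.trough_depth,
            "ptp_occ_cmh2o_s": p.ptp_occ,
            "release_ratio": p.morphology.release_ratio if p.morphology else np.nan,
            "etp_di_uv_s": s.etp_di if s else np.nan,
            "aub_uv_s": s.aub if s else np.nan,
            "auc_tot_uv_s": s.auc_tot if s else np.nan,
            "snr_pct": s.snr_pct if s else np.nan,
            "tdi_ratio_pct": s.tdi_ratio if s and s.tdi_ratio is not None else np.nan,
            "bell_error_pct": s.bell_error_pct if s else np.nan,
        }
        for name, verdict in r.verdicts.items():
            row[f"included_{name}"] = verdict.included
            row[f"failed_{name}"] = "|".join(sorted(verdict.failed_criteria))
        rows.append(row)
    return pd.DataFrame(rows)
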