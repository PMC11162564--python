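"""PEEP-trial analysis: normalisation, NMCdi, CoV and trend summaries.

Within one incremental PEEP trial, PTPocc and ETPdi of the included
manoeuvres are normalised to their medians at the reference PEEP level
(default 9 cmH2O, the level shared by every protocol arm), and the
neuromuscular coupling index per manoeuvre is

    NMCdi_norm = PTPocc_norm / ETPdi_norm.

Repeatability is summarised by the coefficient of variation

    CoV = sqrt(MSE_w) / grand_mean,

with MSE_w the mean within-group sample variance over (trial, PEEP-level)
groups.  The PEEP trend is a linear slope of per-level median normalised
NMCdi (x100, i.e. percentage points) against PEEP with cluster-robust
standard errors over trials; a full estimating-equation fit is deliberately
delegated to general statistics tooling and not re-implemented here.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, QualityError
from .events import ManoeuvreRecord

__all__ = [
    "PeepTrialResult",
    "CovSummary",
    "SlopeSummary",
    "normalise_trial",
    "compute_cov",
    "estimate_peep_slope",
]


@dataclass
class PeepTrialResult:
    """Normalised per-level results of one PEEP trial.

    ``per_level`` maps PEEP (cmH2O) to a list of
    ``(ptp_norm, etp_norm, nmc_norm)`` tuples, one per included manoeuvre.
    ``complete`` is True when every expected level has at least one
    adequate manoeuvre.
    """

    trial_id: str
    per_level: dict
    reference_peep: float
    complete: bool
    expected_levels: tuple = ()

    def nmc_values(self, peep: float) -> list:
        return [v[2] for v in self.per_level.get(peep, [])]

    def level_medians(self) -> pd.DataFrame:
        rows = [
            {
                "peep": peep,
                "n": len(vals),
                "ptp_norm_median": float(np.median([v[0] for v in vals])),
                "etp_norm_median": float(np.median([v[1] for v in vals])),
                "nmc_norm_median": float(np.median([v[2] for v in vals])),
            }
            for peep, vals in sorted(self.per_level.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class CovSummary:
    cov: float        # dimensionless
    mse_w: float
    grand_mean: float
    n_groups: int
    n_total: int

    @property
    def cov_pct(self) -> float:
        return 100.0 * self.cov


@dataclass
class SlopeSummary:
    slope_pp_per_cmh2o: float
    stderr: float
    n_trials: int
    n_points: int


def normalise_trial(
    records: Sequence[ManoeuvreRecord],
    reference_peep: float = 9.0,
    trial_id: str = "",
    expected_levels: Optional[Sequence[float]] = None,
) -> PeepTrialResult:
    """Normalise included manoeuvres of one trial to the reference level.

    ``records`` must already be filtered to the included manoeuvres of one
    quality profile and carry ptp/etp values.
    """
    usable = [
        r
        for r in records
        if r.pocc.ptp_occ is not None and r.pocc.ptp_occ > 0
        and r.seadi is not None and r.seadi.etp_di is not None and r.seadi.etp_di > 0
    ]
    ref = [r for r in usable if r.peep_level == reference_peep]
    if not ref:
        raise QualityError(
            f"trial {trial_id!r}: no adequate manoeuvre at the reference PEEP "
            f"({reference_peep} cmH2O); trial unusable"
        )
    ptp_ref = float(np.median([r.pocc.ptp_occ for r in ref]))
    etp_ref = float(np.median([r.seadi.etp_di for r in ref]))
    per_level: dict = {}
    for r in usable:
        ptp_n = r.pocc.ptp_occ / ptp_ref
        etp_n = r.seadi.etp_di / etp_ref
        per_level.setdefault(r.peep_level, []).append((ptp_n, etp_n, ptp_n / etp_n))
    levels = tuple(sorted(expected_levels)) if expected_levels else tuple(sorted(per_level))
    complete = all(lvl in per_level for lvl in levels)
    return PeepTrialResult(
        trial_id=trial_id,
        per_level=per_level,
        reference_peep=reference_peep,
        complete=complete,
        expected_levels=levels,
    )


def compute_cov(groups: Sequence[Sequence[float]]) -> CovSummary:
    """Coefficient of variation from grouped values.

    ``mse_w`` is the mean of the within-group sample variances (ddof=1)
    over groups with at least two values; singletons still enter the grand
    mean.  Errors if every group is a singleton or the grand mean is 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if not groups:
        raise DataError("compute_cov: no groups")
    variances = [float(g.var(ddof=1)) for g in groups if g.size >= 2]
    if not variances:
        raise DataError("compute_cov: all groups are singletons; MSE_w undefined")
    all_vals = np.concatenate(groups)
    grand_mean = float(all_vals.mean())
    if grand_mean == 0:
        raise DataError("compute_cov: grand mean is zero")
    mse_w = float(np.mean(variances))
    return CovSummary(
        cov=float(np.sqrt(mse_w) / grand_mean),
        mse_w=mse_w,
        grand_mean=grand_mean,
        n_groups=len(groups),
        n_total=int(all_vals.size),
    )


def estimate_peep_slope(trials: Sequence[PeepTrialResult]) -> SlopeSummary:
    """Linear PEEP trend of normalised NMCdi in percentage points per cmH2O.

    Fits per-level median NMCdi_norm (x100) against PEEP by OLS; standard
    errors are cluster-robust over trials when at least two trials are
    given, classical otherwise.
    """
    import statsmodels.api as sm

    rows = []
    for tr in trials:
        for peep, vals in tr.per_level.items():
            rows.append(
                {"trial": tr.trial_id, "peep": float(peep),
                 "nmc_pp": 100.0 * float(np.median([v[2] for v in vals]))}
            )
    df = pd.DataFrame(rows)
    if df.empty or df["peep"].nunique() < 2:
        raise DataError("estimate_peep_slope: need data spanning >= 2 PEEP levels")
    X = sm.add_constant(df["peep"].to_numpy())
    model = sm.OLS(df["nmc_pp"].to_numpy(), X)
    n_trials = df["trial"].nunique()
    if n_trials >= 2:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": df["trial"].to_numpy()})
    else:
        fit = model.fit()
    return SlopeSummary(
        slope_pp_per_cmh2o=float(fit.params[1]),
        stderr=float(fit.bse[1]),
        n_trials=int(n_trials),
        n_points=int(len(df)),
    )


# end-to-end orchestration lives in pipeline.py; re-exported here because
# trial analysis is its natural entry point
from .pipeline import PipelineResult, run_pipeline  # noqa: E402,F401
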