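"""Structured, schema-validated run configuration.

Every tunable of the pipeline lives here, grouped per stage; unknown keys
are rejected so a typo cannot silently fall back to a default.  The full
effective configuration is serialised into every run log.
"""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

__all__ = [
    "PreprocessingConfig", "BaselineConfig", "EventsConfig",
    "QualityConfig", "AnalysisConfig", "RunConfig", "load_config",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessingConfig(_Section):
    low_hz: float = 20.0
    high_hz: float = 500.0
    order: int = 3
    gate_window_s: float = 0.1
    gate_fill: str = "neighbourhood"
    gate_passes: int = 1
    rms_window_s: float = 0.2


class BaselineConfig(_Section):
    percentile: float = 33.0
    basic_window_s: float = 5.0      # Paw baseline window
    advanced_window_s: float = 7.5   # variance-amplified sEAdi baseline window
    step_s: float = 0.2
    variance_gain: float = 0.25


class EventsConfig(_Section):
    min_depth_cmh2o: float = 2.0
    min_duration_s: float = 0.2
    search_pad_s: float = 0.5
    level_settle_s: float = 5.0      # skipped after each PEEP step change
    window_gap_s: float = 2.0        # gap that separates occlusion windows
    use_meta_windows: bool = True    # honour session.meta["occlusion_windows"]


class QualityConfig(_Section):
    profile: str = "tolerant"        # manual | tolerant | strict
    tdi_window_s: float = 15.0
    tdi_min_peak_distance_s: float = 0.25
    tdi_rel_height: float = 0.2
    # optional overrides of the built-in profile thresholds
    tdi_max_pct: float | None = None
    snr_min_pct: float | None = None
    aub_max_pct: float | None = None
    bell_error_max_pct: float | None = None
    pocc_release_ratio_max: float | None = None


class AnalysisConfig(_Section):
    reference_peep: float = 9.0


class RunConfig(_Section):
    seed: int = 0
    trial_id: str = "trial"
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    baseline: BaselineConfig = Field(default_factory=BaselineConfig)
    events: EventsConfig = Field(default_factory=EventsConfig)
    quality: QualityConfig = Field(default_factory=QualityConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    def resolved_profile(self):
        """The active QualityProfile with any configured overrides applied."""
        from .quality import QualityProfile, builtin_profiles

        profiles = builtin_profiles()
        if self.quality.profile not in profiles:
            raise ConfigError(
                f"unknown quality profile {self.quality.profile!r}; choose from {sorted(profiles)}"
            )
        base = profiles[self.quality.profile]
        overrides = {
            k: getattr(self.quality, k)
            for k in ("tdi_max_pct", "snr_min_pct", "aub_max_pct",
                      "bell_error_max_pct", "pocc_release_ratio_max")
            if getattr(self.quality, k) is not None
        }
        if not overrides:
            return base
        return QualityProfile(name=base.name, **{
            "tdi_max_pct": base.tdi_max_pct, "snr_min_pct": base.snr_min_pct,
            "aub_max_pct": base.aub_max_pct, "bell_error_max_pct": base.bell_error_max_pct,
            "pocc_release_ratio_max": base.pocc_release_ratio_max, **overrides,
        })


def load_config(path=None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML configuration (or an in-memory mapping)."""
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**(data or {}))
    except ValidationError as exc:
        bad = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {bad}") from exc
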