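"""Synthetic recording sessions with ground truth.

The generator emulates an incremental PEEP trial on pressure-support
ventilation: stepwise PEEP levels (+2 cmH2O per step), cyclic support
breaths, and three end-expiratory occlusion manoeuvres per level appearing
as negative Paw deflections.  The diaphragm sEMG channel is broadband
(20–500 Hz shaped) Gaussian noise whose instantaneous RMS is modulated by
inspiratory bursts, contaminated by a periodic QRS template; the ECG
channel carries the same beat sequence.

Each named defect mode breaks exactly one quality criterion by design:

* ``low_snr`` — burst amplitude calibrated to an envelope-domain SNR
  below the tolerant cut-off;
* ``high_aub`` — moderate SNR, so the area under the moving baseline
  dominates the total area under the peak;
* ``cardiac_locked`` — bursts occur at heart beats instead of breaths;
* ``non_bell`` — bursts are spike complexes instead of bells;
* ``abrupt_pocc`` — the occlusion pressure returns to PEEP instantly.

Burst amplitude is calibrated *after* the 200 ms RMS envelope: the raw
modulation depth is solved by bisection so that the pipeline-measured
envelope SNR (peak relative to the variance-amplified moving baseline)
hits ``target_snr_pct``.  All randomness comes from
``numpy.random.default_rng(seed)`` (PCG64), so a seed fixes every sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import scipy.signal
import yaml

from .baseline import variance_amplified_baseline
from .errors import ConfigError, ParameterError
from .io_session import RecordingSession, SignalTrace

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "available_presets",
    "preset_spec",
    "simulate_ecg",
    "simulate_semg",
    "simulate_ventilator",
    "simulate_session",
]

DEFECTS = ("none", "low_snr", "high_aub", "cardiac_locked", "non_bell", "abrupt_pocc", "mixed")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterisation of one synthetic session."""

    seed: int = 0
    duration_per_level_s: float = 40.0
    peep_levels: tuple = (5.0, 7.0, 9.0, 11.0)
    occlusions_per_level: int = 3
    heart_rate_bpm: float = 75.0
    resp_rate_bpm: float = 15.0
    burst_width_s: float = 0.25        # Gaussian sigma (bell) / half width (square)
    burst_shape: str = "bell"          # bell | square | double_spike
    noise_floor_uv: float = 5.0
    target_snr_pct: float = 800.0
    ecg_amplitude_uv: float = 120.0    # QRS bleed-through into the EMG channel
    pocc_depth_cmh2o: float = 10.0
    pocc_duration_s: float = 1.0
    pocc_release: str = "smooth"       # smooth | abrupt
    ps_above_cmh2o: float = 8.0
    insp_time_s: float = 1.0
    nmc_slope_pp_per_cmh2o: float = 4.9
    reference_peep: float = 9.0
    defect: str = "none"
    emg_rate: float = 2048.0
    vent_rate: float = 100.0
    rr_jitter_frac: float = 0.02
    burst_time_jitter_s: float = 0.05
    burst_amp_jitter_sd: float = 0.05
    paw_noise_cmh2o: float = 0.05
    baseline_variance_gain: float = 0.25  # must match the analysis default

    def __post_init__(self):
        if not (30 <= self.heart_rate_bpm <= 180):
            raise ParameterError("heart_rate_bpm must be within [30, 180]")
        if self.defect not in DEFECTS:
            raise ParameterError(f"unknown defect mode {self.defect!r}")
        if self.burst_shape not in ("bell", "square", "double_spike"):
            raise ParameterError(f"unknown burst shape {self.burst_shape!r}")
        if min(self.peep_levels, default=0) < 0 or not self.peep_levels:
            raise ParameterError("peep_levels must be non-empty and non-negative")


@dataclass
class GroundTruth:
    """Programmed quantities the pipeline should recover."""

    beat_times: np.ndarray
    burst_centres: np.ndarray            # occluded-breath bursts only
    burst_amp_factors: np.ndarray        # per-manoeuvre amplitude multiplier
    occlusion_windows: list              # (start_s, end_s) per manoeuvre
    manoeuvre_levels: np.ndarray         # PEEP per manoeuvre
    defect_labels: list                  # per-manoeuvre defect tag
    programmed_ptp: np.ndarray           # dip area below PEEP, cmH2O*s
    programmed_nmc_per_level: dict       # PEEP -> normalised NMC factor
    modulation_depth: float              # solved raw RMS modulation


# ---------------------------------------------------------------- presets

def available_presets() -> dict:
    with resources.files("nmcdi").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def preset_spec(name: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Build a ScenarioSpec from a named preset, with optional overrides."""
    presets = available_presets()
    if name not in presets:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    params = dict(presets[name] or {})
    params.update(overrides)
    if "peep_levels" in params:
        params["peep_levels"] = tuple(float(p) for p in params["peep_levels"])
    return ScenarioSpec(seed=seed, **params)


# ------------------------------------------------------------- schedules

def nmc_factor(spec: ScenarioSpec, peep: float) -> float:
    """Programmed normalised NMC at one level: linear decline of
    ``nmc_slope_pp_per_cmh2o`` percentage points per cmH2O from 1 at the
    reference PEEP."""
    return 1.0 - spec.nmc_slope_pp_per_cmh2o / 100.0 * (peep - spec.reference_peep)


def _occlusion_centres(spec: ScenarioSpec) -> np.ndarray:
    """Nominal occlusion centres: evenly spread over the second half of each
    level, clear of the step change and the trace edges."""
    dur = spec.duration_per_level_s
    k = spec.occlusions_per_level
    rel = dur * (0.45 + 0.42 * np.arange(k) / max(k - 1, 1))
    return np.concatenate([i * dur + rel for i in range(len(spec.peep_levels))])


def _breath_times(spec: ScenarioSpec) -> np.ndarray:
    total = spec.duration_per_level_s * len(spec.peep_levels)
    period = 60.0 / spec.resp_rate_bpm
    return np.arange(2.0, total - 2.0, period)


# ------------------------------------------------------------ ECG channel

_TEMPLATE_T_MS = np.array([-40.0, -28.0, -20.0, -12.0, 0.0, 10.0, 18.0, 40.0])
_TEMPLATE_V = np.array([0.0, 0.0, -0.12, 0.0, 1.0, -0.25, 0.0, 0.0])


def _qrs_waveform(t: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    """Unit-R-amplitude triangular biphasic QRS train (~80 ms wide)."""
    out = np.zeros_like(t)
    rate = 1.0 / (t[1] - t[0])
    half = int(round(0.04 * rate))
    tpl_rel = (np.arange(-half, half + 1) / rate) * 1000.0
    tpl = np.interp(tpl_rel, _TEMPLATE_T_MS, _TEMPLATE_V)
    n = t.size
    for bt in beat_times:
        c = int(round((bt - t[0]) * rate))
        i0, i1 = c - half, c + half + 1
        j0, j1 = max(i0, 0), min(i1, n)
        if j1 > j0:
            out[j0:j1] += tpl[j0 - i0 : j1 - i0]
    return out


def simulate_ecg(spec: ScenarioSpec, rng=None) -> tuple:
    """ECG channel (2048 Hz) and the true beat times."""
    rng = rng or np.random.default_rng(spec.seed)
    total = spec.duration_per_level_s * len(spec.peep_levels)
    rr = 60.0 / spec.heart_rate_bpm
    n_beats = int(total / rr) + 2
    gaps = rr * (1.0 + spec.rr_jitter_frac * rng.standard_normal(n_beats))
    beat_times = 0.4 + np.cumsum(np.maximum(gaps, 0.25)) - gaps[0]
    beat_times = beat_times[beat_times < total - 0.1]
    t = np.arange(int(round(total * spec.emg_rate))) / spec.emg_rate
    amp = 800.0  # uV, R amplitude on the dedicated lead
    ecg = amp * _qrs_waveform(t, beat_times) + 8.0 * rng.standard_normal(t.size)
    trace = SignalTrace(samples=ecg, rate=spec.emg_rate, label="ecg", units="uV")
    return trace, beat_times


# ------------------------------------------------------------ EMG channel

def _burst_profile(t: np.ndarray, centre: float, spec: ScenarioSpec, shape: str) -> np.ndarray:
    w = spec.burst_width_s
    if shape == "bell":
        return np.exp(-((t - centre) ** 2) / (2.0 * w**2))
    if shape == "square":
        return ((t >= centre - w) & (t < centre + w)).astype(float)
    # double_spike: two narrow spikes on a low pedestal; the pedestal keeps
    # the whole complex above the moving baseline so the peak bounds span
    # both spikes and the bell fit sees the full non-bell structure
    s = 0.055
    ped = 0.25 * np.exp(-((t - centre) ** 2) / (2.0 * 0.45**2))
    spikes = np.exp(-((t - centre - 0.30) ** 2) / (2.0 * s**2)) + np.exp(
        -((t - centre + 0.30) ** 2) / (2.0 * s**2)
    )
    return ped + spikes


def _shape_signal(t: np.ndarray, centres, amps, spec: ScenarioSpec, shape: str) -> np.ndarray:
    out = np.zeros_like(t)
    rate = 1.0 / (t[1] - t[0])
    pad = 4.0 * max(spec.burst_width_s, 0.5)
    for c, a in zip(centres, amps):
        i0 = max(0, int((c - pad) * rate))
        i1 = min(t.size, int((c + pad) * rate))
        out[i0:i1] += a * _burst_profile(t[i0:i1], c, spec, shape)
    return out


_CAL_CACHE: dict = {}


def _calibrate_modulation(spec: ScenarioSpec) -> float:
    """Solve the raw RMS modulation depth so that the envelope-domain SNR
    (peak over the variance-amplified moving baseline) at the occluded
    bursts matches ``target_snr_pct``.  Deterministic (expected envelope,
    nominal schedule); cached per scenario geometry."""
    key = (
        spec.duration_per_level_s, spec.peep_levels, spec.occlusions_per_level,
        spec.resp_rate_bpm, spec.heart_rate_bpm, spec.burst_width_s, spec.burst_shape,
        spec.target_snr_pct, spec.defect, spec.baseline_variance_gain,
    )
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    fd = 128.0
    total = spec.duration_per_level_s * len(spec.peep_levels)
    t = np.arange(int(total * fd)) / fd
    occ = _occlusion_centres(spec)
    if spec.defect == "cardiac_locked":
        rr = 60.0 / spec.heart_rate_bpm
        centres = np.arange(0.4, total - 0.1, rr)
        meas_at = np.array([centres[np.argmin(np.abs(centres - c))] for c in occ])
    else:
        centres = _breath_times(spec)
        meas_at = occ
    shape = _shape_signal(t, np.unique(np.concatenate([centres, occ])),
                          np.ones(np.unique(np.concatenate([centres, occ])).size),
                          spec, spec.burst_shape)
    w = max(1, int(round(0.2 * fd)))
    kernel = np.ones(w) / w

    def measured_snr(m: float) -> float:
        mod_sq = (1.0 + m * shape) ** 2
        env = np.sqrt(np.convolve(mod_sq, kernel, mode="same"))
        env_tr = SignalTrace(samples=env, rate=fd, label="cal")
        base = variance_amplified_baseline(
            env_tr, window_s=7.5, step_s=0.2, variance_gain=spec.baseline_variance_gain
        )
        vals = []
        for c in meas_at:
            i0 = max(0, int((c - 0.6) * fd))
            i1 = min(env.size, int((c + 0.6) * fd))
            j = i0 + int(np.argmax(env[i0:i1] - base.samples[i0:i1]))
            vals.append(100.0 * env[j] / base.samples[j])
        return float(np.median(vals))

    lo, hi = 1e-3, 2000.0
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if measured_snr(mid) < spec.target_snr_pct:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.001:
            break
    m = float(np.sqrt(lo * hi))
    _CAL_CACHE[key] = m
    return m


_NOISE_SOS = None


def _shaped_noise(n: int, rate: float, rng) -> np.ndarray:
    """Unit-RMS Gaussian noise shaped to the 20–500 Hz analysis band, so the
    analysis bandpass leaves the scenario calibration unchanged."""
    global _NOISE_SOS
    if _NOISE_SOS is None or _NOISE_SOS[0] != rate:
        sos = scipy.signal.butter(3, [20.0, 500.0], btype="bandpass", fs=rate, output="sos")
        _NOISE_SOS = (rate, sos)
    x = scipy.signal.sosfiltfilt(_NOISE_SOS[1], rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def simulate_semg(
    spec: ScenarioSpec,
    beat_times: np.ndarray,
    burst_centres: np.ndarray,
    burst_amp_factors: np.ndarray,
    rng=None,
) -> SignalTrace:
    """sEMG channel: RMS-modulated shaped noise + QRS bleed-through."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    total = spec.duration_per_level_s * len(spec.peep_levels)
    t = np.arange(int(round(total * spec.emg_rate))) / spec.emg_rate
    m = _calibrate_modulation(spec)
    shape = _shape_signal(t, burst_centres, burst_amp_factors, spec, spec.burst_shape)
    noise = _shaped_noise(t.size, spec.emg_rate, rng)
    emg = spec.noise_floor_uv * (1.0 + m * shape) * noise
    emg += spec.ecg_amplitude_uv * _qrs_waveform(t, beat_times)
    return SignalTrace(samples=emg, rate=spec.emg_rate, label="emg_di", units="uV")


# ------------------------------------------------------ ventilator channels

def simulate_ventilator(spec: ScenarioSpec, rng=None) -> tuple:
    """Paw / flow / volume traces plus occlusion ground truth.

    Returns ``(paw, flow, volume, occlusion_windows, programmed_ptp,
    depth_factors)``; occluded breaths are negative dips from PEEP whose
    area per level encodes the programmed NMC decline.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    total = spec.duration_per_level_s * len(spec.peep_levels)
    n = int(round(total * spec.vent_rate))
    t = np.arange(n) / spec.vent_rate
    dur = spec.duration_per_level_s

    peep = np.zeros(n)
    for i, p in enumerate(spec.peep_levels):
        peep[(t >= i * dur) & (t < (i + 1) * dur)] = p
    paw = peep.copy()

    occ = _occlusion_centres(spec)
    occ_level = np.array([spec.peep_levels[int(c // dur)] for c in occ])
    breaths = _breath_times(spec)
    occluded_breaths = set()
    for c in occ:
        occluded_breaths.add(float(breaths[np.argmin(np.abs(breaths - c))]))

    # pressure-support inspirations on non-occluded breaths
    ti = spec.insp_time_s
    for b in breaths:
        if float(b) in occluded_breaths:
            continue
        i0, i1 = int(b * spec.vent_rate), int((b + ti) * spec.vent_rate)
        i0, i1 = max(i0, 0), min(i1, n)
        tau = t[i0:i1] - b
        paw[i0:i1] += spec.ps_above_cmh2o * np.sin(np.pi * tau / ti) ** 2

    windows = []
    ptp_prog = np.zeros(occ.size)
    depth_factors = np.ones(occ.size)
    D = spec.pocc_duration_s
    for k, c in enumerate(occ):
        factor = nmc_factor(spec, occ_level[k])
        depth = spec.pocc_depth_cmh2o * factor
        depth_factors[k] = factor
        i0 = int((c - D / 2) * spec.vent_rate)
        i1 = int((c + D / 2) * spec.vent_rate)
        i0, i1 = max(i0, 0), min(i1, n)
        tau = t[i0:i1] - (c - D / 2)
        if spec.pocc_release == "abrupt" or spec.defect == "abrupt_pocc":
            rise = 0.75 * D
            dip = np.where(tau < rise, depth * np.sin(np.pi * tau / (2.0 * rise)) ** 2, 0.0)
            ptp_prog[k] = depth * rise / 2.0
        else:
            dip = depth * np.sin(np.pi * tau / D) ** 2
            ptp_prog[k] = depth * D / 2.0
        paw[i0:i1] -= dip
        windows.append((c - D / 2 - 0.3, c + D / 2 + 0.3))

    paw += spec.paw_noise_cmh2o * rng.standard_normal(n)

    # cosmetic flow/volume: half-sine inspiratory flow, passive decay, zero
    # during occlusions (closed airway)
    flow = np.zeros(n)
    for b in breaths:
        if float(b) in occluded_breaths:
            continue
        i0, i1 = max(int(b * spec.vent_rate), 0), min(int((b + ti) * spec.vent_rate), n)
        flow[i0:i1] += 0.6 * np.sin(np.pi * (t[i0:i1] - b) / ti)
        j0, j1 = i1, min(int((b + ti + 1.2) * spec.vent_rate), n)
        flow[j0:j1] -= 0.5 * np.exp(-(t[j0:j1] - b - ti) / 0.4)
    volume = np.cumsum(flow) / spec.vent_rate
    volume -= np.minimum.accumulate(volume)

    mk = lambda x, lbl, u: SignalTrace(samples=x, rate=spec.vent_rate, label=lbl, units=u)
    return (
        mk(paw, "paw", "cmH2O"), mk(flow, "flow", "L/s"), mk(volume, "volume", "L"),
        windows, ptp_prog, depth_factors,
    )


# ------------------------------------------------------------ full session

_MIXED_CLASSES = ("clean", "mild_aub", "high_aub")
_MIXED_AMP = {"clean": 1.0, "mild_aub": 0.40, "high_aub": 0.135}
_MIXED_PTP_JITTER_SD = {"clean": 0.0, "mild_aub": 0.25, "high_aub": 0.5}


def simulate_session(spec: ScenarioSpec) -> tuple:
    """Compose ECG, sEMG and ventilator channels on a shared timebase.

    Returns ``(RecordingSession, GroundTruth)``.  Identical specs (same
    seed) produce bit-identical sessions.
    """
    rng = np.random.default_rng(spec.seed)
    ecg, beat_times = simulate_ecg(spec, rng)
    paw, flow, volume, windows, ptp_prog, depth_factors = simulate_ventilator(spec, rng)

    occ = _occlusion_centres(spec)
    breaths = _breath_times(spec)
    labels = [spec.defect] * occ.size
    amp_occ = np.ones(occ.size)

    if spec.defect == "mixed":
        # per level: one clean, one mild (strict-only AUB) and one severe
        # (tolerant-excluded AUB) manoeuvre, in seeded random order, with
        # PTP jitter growing with severity so exclusion genuinely reduces
        # NMC variability
        k = spec.occlusions_per_level
        labels = []
        for lvl in range(len(spec.peep_levels)):
            order = (list(_MIXED_CLASSES) * ((k + 2) // 3))[:k]
            rng.shuffle(order)
            labels.extend(order)
        for i, lab in enumerate(labels):
            amp_occ[i] = _MIXED_AMP[lab]
            jit = _MIXED_PTP_JITTER_SD[lab]
            if jit > 0:
                depth_factors[i] *= float(np.exp(jit * rng.standard_normal()))
        # rescale each dip region so the PTP carries the class jitter
        paw_s = paw.samples.copy()
        D = spec.pocc_duration_s
        base_prog = ptp_prog.copy()
        for i, c in enumerate(occ):
            lvl = spec.peep_levels[int(c // spec.duration_per_level_s)]
            scale = depth_factors[i] / nmc_factor(spec, lvl)
            if abs(scale - 1.0) < 1e-12:
                continue
            i0 = max(int((c - D / 2 - 0.05) * spec.vent_rate), 0)
            i1 = min(int((c + D / 2 + 0.05) * spec.vent_rate), paw_s.size)
            dip = np.maximum(lvl - paw_s[i0:i1], 0.0)
            paw_s[i0:i1] -= (scale - 1.0) * dip
            ptp_prog[i] = base_prog[i] * scale
        paw = replace(paw, samples=paw_s)

    if spec.defect == "cardiac_locked":
        rr = 60.0 / spec.heart_rate_bpm
        total = spec.duration_per_level_s * len(spec.peep_levels)
        centres = np.arange(0.4, total - 0.1, rr)
        amps = np.ones(centres.size)
        truth_centres = np.array([centres[np.argmin(np.abs(centres - c))] for c in occ])
    else:
        jitter = spec.burst_time_jitter_s * rng.standard_normal(breaths.size)
        centres = breaths + jitter
        amps = np.exp(spec.burst_amp_jitter_sd * rng.standard_normal(breaths.size))
        occ_idx = np.array([int(np.argmin(np.abs(breaths - c))) for c in occ])
        centres[occ_idx] = occ + jitter[occ_idx]  # burst rides the occluded effort
        amps[occ_idx] *= amp_occ
        truth_centres = centres[occ_idx]

    emg = simulate_semg(spec, beat_times, centres, amps, rng)

    schedule = [(i * spec.duration_per_level_s, p) for i, p in enumerate(spec.peep_levels)]
    session = RecordingSession(
        emg_di=emg, ecg=ecg, paw=paw, flow=flow, volume=volume,
        peep_schedule=schedule,
        meta={"occlusion_windows": windows, "seed": spec.seed, "defect": spec.defect},
    )
    dur = spec.duration_per_level_s
    truth = GroundTruth(
        beat_times=beat_times,
        burst_centres=truth_centres,
        burst_amp_factors=amp_occ,
        occlusion_windows=windows,
        manoeuvre_levels=np.array([spec.peep_levels[int(c // dur)] for c in occ]),
        defect_labels=labels,
        programmed_ptp=ptp_prog,
        programmed_nmc_per_level={p: nmc_factor(spec, p) for p in spec.peep_levels},
        modulation_depth=_calibrate_modulation(spec),
    )
    return session, truth
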