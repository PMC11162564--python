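import numpy as np
import pytest

from nmcdi import RunConfig, run_pipeline
from nmcdi.io_session import SignalTrace
from nmcdi.synthetic import preset_spec, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_trace(samples, rate=100.0, start=0.0, label="x", units=""):
    return SignalTrace(samples=np.asarray(samples, dtype=float), rate=rate,
                       start_time=start, label=label, units=units)


@pytest.fixture(scope="session")
def clean_session():
    """One clean synthetic session shared across tests (read-only)."""
    return simulate_session(preset_spec("clean", seed=7))


@pytest.fixture(scope="session")
def clean_run(clean_session):
    """Pipeline result on the shared clean session."""
    session, truth = clean_session
    return run_pipeline(session, RunConfig(trial_id="clean7")), truth


def brute_force_rms_envelope(x, rate, window_s):
    """Per-sample centred RMS with the half-open truncated-window convention."""
    x = np.asarray(x, dtype=float)
    w = max(1, int(round(window_s * rate)))
    h_lo, h_hi = w // 2, w - w // 2
    out = np.empty_like(x)
    for i in range(x.size):
        win = x[max(0, i - h_lo): min(x.size, i + h_hi)]
        out[i] = np.sqrt(np.mean(win ** 2))
    return out


def brute_force_baseline_anchors(x, rate, window_s, step_s, percentile, variance_gain=None):
    """Anchor positions/values: sorted-array percentile (+ gain * SD) per
    centred, edge-clipped window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    w = max(1, int(round(window_s * rate)))
    h_lo, h_hi = w // 2, w - w // 2
    step = max(1, int(round(step_s * rate)))
    idx = list(range(0, n, step))
    if idx[-1] != n - 1:
        idx.append(n - 1)
    vals = []
    for i in idx:
        win = np.sort(x[max(0, i - h_lo): min(n, i + h_hi)])
        v = float(np.percentile(win, percentile, method="linear"))
        if variance_gain is not None:
            v += variance_gain * float(win.std())
        vals.append(v)
    return np.array(idx), np.array(vals)
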