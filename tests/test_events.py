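import numpy as np
import pytest

from nmcdi import (
    QualityError,
    compute_etp,
    compute_pocc_morphology,
    compute_ptp,
    detect_occlusions,
    match_seadi_peak,
    select_first_breath,
)
from nmcdi.baseline import BaselineTrace, PeakBounds
from nmcdi.events import PoccEvent
from nmcdi.preprocessing import EnvelopeTrace
from conftest import make_trace

RATE = 100.0


def _flat_base(n, value, rate=RATE, start=0.0):
    return BaselineTrace(samples=np.full(n, float(value)), rate=rate, start_time=start)


def _env(x, rate=RATE, start=0.0):
    return EnvelopeTrace(samples=np.asarray(x, float), rate=rate, start_time=start)


def _paw_with_dip(peep, depth, t_on, t_off, dur=30.0, shape="triangle"):
    t = np.arange(int(dur * RATE)) / RATE
    x = np.full(t.size, float(peep))
    m = (t >= t_on) & (t < t_off)
    tau = (t[m] - t_on) / (t_off - t_on)
    if shape == "triangle":
        x[m] -= depth * (1 - np.abs(2 * tau - 1))
    elif shape == "rect":
        x[m] -= depth
    return make_trace(x, rate=RATE, label="paw")


class TestDetectOcclusions:
    def test_flat_pressure_yields_nothing(self):
        paw = make_trace(np.full(3000, 9.0), rate=RATE)
        assert detect_occlusions(paw, set_peep=9.0) == []

    def test_rectangular_dip_geometry(self):
        paw = _paw_with_dip(9.0, 10.0, 10.0, 11.0, shape="rect")
        events = detect_occlusions(paw, set_peep=9.0)
        assert len(events) == 1
        e = events[0]
        assert e.trough_depth == pytest.approx(10.0, abs=0.01)
        assert e.bounds.duration == pytest.approx(1.0, abs=2.5 / RATE)

    def test_generator_truth_recovered(self, clean_run):
        """Three occlusions per PEEP level, troughs within 50 ms of truth."""
        result, truth = clean_run
        troughs = np.array([r.pocc.trough_time for r in result.records])
        assert troughs.size == truth.burst_centres.size == 12
        for w0, w1 in truth.occlusion_windows:
            centre = (w0 + w1) / 2
            assert np.min(np.abs(troughs - centre)) < 0.05


class TestFirstBreath:
    def _ev(self, t):
        b = PeakBounds(onset_time=t - 0.3, peak_time=t, offset_time=t + 0.3)
        return PoccEvent(bounds=b, trough_time=t, trough_depth=5.0, set_peep=9.0)

    def test_two_dips_in_one_window_keeps_first(self):
        evs = [self._ev(10.0), self._ev(11.0)]
        kept = select_first_breath(evs, [(9.0, 12.0)])
        assert [e.trough_time for e in kept] == [10.0]

    def test_one_dip_per_window_unchanged(self):
        evs = [self._ev(10.0), self._ev(20.0)]
        kept = select_first_breath(evs, [(9.0, 12.0), (19.0, 22.0)])
        assert [e.trough_time for e in kept] == [10.0, 20.0]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_argmin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        windows = [(10.0 * k, 10.0 * k + 8.0) for k in range(4)]
        evs = sorted(
            (self._ev(float(rng.uniform(w0 + 0.5, w1 - 0.5))) for w0, w1 in windows for _ in range(rng.integers(0, 4))),
            key=lambda e: e.trough_time,
        )
        kept = select_first_breath(evs, windows)
        expect = []
        for w0, w1 in windows:
            inside = [e for e in evs if w0 <= e.trough_time < w1]
            if inside:
                expect.append(min(inside, key=lambda e: e.bounds.onset_time))
        assert [e.trough_time for e in kept] == [e.trough_time for e in expect]


class TestPtp:
    def test_triangle_dip_area(self):
        paw = _paw_with_dip(9.0, 8.0, 10.0, 12.0)  # depth 8, base width 2
        base = _flat_base(paw.n, 9.0)
        events = detect_occlusions(paw, 9.0, paw_baseline=base)
        ev = compute_ptp(paw, base, events[0])
        assert ev.ptp_occ == pytest.approx(8.0 * 2.0 / 2.0, rel=0.01)

    def test_zero_deflection_is_invalid(self):
        paw = make_trace(np.full(500, 9.0), rate=RATE)
        base = _flat_base(500, 9.0)
        b = PeakBounds(onset_time=1.0, peak_time=2.0, offset_time=3.0)
        ev = PoccEvent(bounds=b, trough_time=2.0, trough_depth=0.0, set_peep=9.0)
        out = compute_ptp(paw, base, ev)
        assert not out.valid

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oversampled_quadrature(self, seed):
        """Trapezoid at 100 Hz matches a 10x-oversampled Riemann sum within 0.5%."""
        rng = np.random.default_rng(seed)
        d, w = rng.uniform(4, 12), rng.uniform(0.8, 2.0)
        t_on = 10.0
        f = lambda t: 9.0 - d * np.sin(np.clip((t - t_on) / w, 0, 1) * np.pi) ** 2
        t_lo = np.arange(int(30 * RATE)) / RATE
        paw = make_trace(f(t_lo), rate=RATE)
        base = _flat_base(paw.n, 9.0)
        events = detect_occlusions(paw, 9.0, paw_baseline=base)
        ev = compute_ptp(paw, base, events[0])
        hi = 10 * RATE
        t_hi = np.arange(int(30 * hi)) / hi
        m = (t_hi >= ev.bounds.onset_time) & (t_hi <= ev.bounds.offset_time)
        oracle = np.sum(np.maximum(9.0 - f(t_hi[m]), 0.0)) / hi
        assert ev.ptp_occ == pytest.approx(oracle, rel=0.005)


class TestSeadiMatching:
    def _burst_env(self, centre, amp=8.0, sigma=0.3, floor=1.0, dur=20.0, rate=RATE):
        t = np.arange(int(dur * rate)) / rate
        return _env(floor + amp * np.exp(-((t - centre) ** 2) / (2 * sigma**2)), rate=rate)

    def _event(self, t):
        b = PeakBounds(onset_time=t - 0.5, peak_time=t, offset_time=t + 0.5)
        return PoccEvent(bounds=b, trough_time=t, trough_depth=8.0, set_peep=9.0)

    def test_burst_centred_in_occlusion_found(self):
        env = self._burst_env(10.0)
        peak = match_seadi_peak(env, _flat_base(env.n, 1.2), self._event(10.05))
        assert peak.bounds.peak_time == pytest.approx(10.0, abs=0.1)

    def test_envelope_below_baseline_is_quality_error(self):
        env = _env(np.full(2000, 0.5))
        with pytest.raises(QualityError):
            match_seadi_peak(env, _flat_base(2000, 1.0), self._event(10.0))

    def test_larger_of_two_bursts_selected(self):
        t = np.arange(int(20 * RATE)) / RATE
        x = 1.0 + 4 * np.exp(-((t - 9.8) ** 2) / 0.02) + 8 * np.exp(-((t - 10.4) ** 2) / 0.02)
        peak = match_seadi_peak(_env(x), _flat_base(t.size, 1.2), self._event(10.1))
        assert peak.bounds.peak_time == pytest.approx(10.4, abs=0.05)


class TestEtp:
    def test_gaussian_bump_area(self):
        rate = 2048.0
        t = np.arange(int(20 * rate)) / rate
        a, mu, sig = 6.0, 10.0, 0.3
        env = _env(2.0 + a * np.exp(-((t - mu) ** 2) / (2 * sig**2)), rate=rate)
        base = _flat_base(t.size, 2.0, rate=rate)
        peak = match_seadi_peak(env, base, TestSeadiMatching()._event(mu))
        peak = compute_etp(env, base, peak)
        assert peak.etp_di == pytest.approx(a * sig * np.sqrt(2 * np.pi), rel=0.01)

    def test_zero_baseline_means_aub_zero(self):
        t = np.arange(int(10 * RATE)) / RATE
        env = _env(np.exp(-((t - 5) ** 2) / 0.5) + 0.01)
        base = _flat_base(t.size, 0.0)
        b = PeakBounds(onset_time=3.0, peak_time=5.0, offset_time=7.0)
        from nmcdi.events import SEAdiPeak

        peak = SEAdiPeak(bounds=b, peak_value=1.0, baseline_at_peak=0.0)
        out = compute_etp(env, base, peak)
        assert out.aub == 0.0
        assert out.etp_di == pytest.approx(out.auc_tot, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_identity_and_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rate = 400.0
        coeffs = rng.uniform(0.5, 2.0, 3)
        f = lambda t: 2.0 + coeffs[0] * np.exp(-((t - 5) ** 2) / (2 * coeffs[1] ** 2)) + 0.3 * np.sin(coeffs[2] * t)
        t = np.arange(int(10 * rate)) / rate
        env = _env(f(t), rate=rate)
        base = _flat_base(t.size, 2.2, rate=rate)
        from nmcdi.events import SEAdiPeak

        b = PeakBounds(onset_time=3.5, peak_time=5.0, offset_time=6.5)
        peak = compute_etp(env, base, SEAdiPeak(bounds=b, peak_value=float(f(5.0)), baseline_at_peak=2.2))
        assert peak.auc_tot == pytest.approx(peak.etp_di + peak.aub, rel=1e-9)
        hi = 10 * rate
        th = np.arange(int(10 * hi)) / hi
        m = (th >= b.onset_time) & (th <= b.offset_time)
        assert peak.etp_di == pytest.approx(np.sum(np.maximum(f(th[m]) - 2.2, 0)) / hi, rel=0.005)
        assert peak.aub == pytest.approx(np.sum(np.minimum(f(th[m]), 2.2)) / hi, rel=0.005)

    def test_linearity_in_amplitude(self, rng):
        rate = 400.0
        t = np.arange(int(10 * rate)) / rate
        x = 1.0 + np.exp(-((t - 5) ** 2) / 0.3)
        from nmcdi.events import SEAdiPeak

        b = PeakBounds(onset_time=4.0, peak_time=5.0, offset_time=6.0)
        base0 = _flat_base(t.size, 0.0, rate=rate)
        p1 = compute_etp(_env(x, rate=rate), base0, SEAdiPeak(bounds=b, peak_value=2.0, baseline_at_peak=0.0))
        p2 = compute_etp(_env(2 * x, rate=rate), base0, SEAdiPeak(bounds=b, peak_value=4.0, baseline_at_peak=0.0))
        assert p2.etp_di == pytest.approx(2 * p1.etp_di, rel=1e-12)
        assert p2.auc_tot == pytest.approx(2 * p1.auc_tot, rel=1e-12)

    def test_shift_invariance_of_ptp_and_etp(self, rng):
        """Adding a constant to signal and baseline leaves the products unchanged."""
        rate = 400.0
        t = np.arange(int(10 * rate)) / rate
        x = 1.0 + np.exp(-((t - 5) ** 2) / 0.3) + 0.05 * rng.standard_normal(t.size)
        from nmcdi.events import SEAdiPeak

        b = PeakBounds(onset_time=4.0, peak_time=5.0, offset_time=6.0)
        base1 = _flat_base(t.size, 1.0, rate=rate)
        base2 = _flat_base(t.size, 11.0, rate=rate)
        p1 = compute_etp(_env(x, rate=rate), base1, SEAdiPeak(bounds=b, peak_value=2.0, baseline_at_peak=1.0))
        p2 = compute_etp(_env(x + 10, rate=rate), base2, SEAdiPeak(bounds=b, peak_value=12.0, baseline_at_peak=11.0))
        assert p2.etp_di == pytest.approx(p1.etp_di, rel=1e-9)


class TestMorphology:
    def _detected(self, paw, base):
        events = detect_occlusions(paw, 9.0, paw_baseline=base)
        assert events
        return compute_pocc_morphology(paw, base, compute_ptp(paw, base, events[0]))

    def test_symmetric_triangle_ratio_near_one(self):
        paw = _paw_with_dip(9.0, 8.0, 10.0, 12.0)
        ev = self._detected(paw, _flat_base(paw.n, 9.0))
        assert ev.morphology.release_ratio == pytest.approx(1.0, rel=0.05)

    def test_instantaneous_release_ratio_large(self):
        t = np.arange(int(30 * RATE)) / RATE
        x = np.full(t.size, 9.0)
        m = (t >= 10.0) & (t < 11.0)
        x[m] -= 8.0 * np.sin(np.pi * (t[m] - 10.0) / 2.0)  # ramp down, then step back
        paw = make_trace(x, rate=RATE)
        ev = self._detected(paw, _flat_base(paw.n, 9.0))
        assert ev.morphology.release_ratio > 5.0
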