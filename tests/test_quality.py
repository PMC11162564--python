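import numpy as np
import pytest

from nmcdi import (
    QualityError,
    apply_profile,
    builtin_profiles,
    compute_bell_error_pct,
    compute_snr_pct,
    compute_tdi_ratio,
    summarise_exclusions,
)
from nmcdi.baseline import BaselineTrace, PeakBounds
from nmcdi.events import ManoeuvreRecord, PoccEvent, PoccMorphology, SEAdiPeak
from nmcdi.preprocessing import EnvelopeTrace, QrsEventSeries


def _flat_base(n, value, rate=100.0):
    return BaselineTrace(samples=np.full(n, float(value)), rate=rate)


def _env(x, rate=100.0):
    return EnvelopeTrace(samples=np.asarray(x, float), rate=rate)


def _record(release=1.0, snr=200.0, tdi=300.0, aub_frac=0.2, bell=10.0):
    b = PeakBounds(onset_time=1.0, peak_time=2.0, offset_time=3.0)
    pocc = PoccEvent(
        bounds=b, trough_time=2.0, trough_depth=8.0, set_peep=9.0, ptp_occ=5.0,
        morphology=PoccMorphology(10.0, 10.0 * release, release) if release is not None else None,
    )
    peak = SEAdiPeak(
        bounds=b, peak_value=snr / 100.0, baseline_at_peak=1.0,
        etp_di=(1 - aub_frac), aub=aub_frac, auc_tot=1.0,
        tdi_ratio=tdi, snr_pct=snr, bell_error_pct=bell,
    )
    return ManoeuvreRecord(pocc=pocc, seadi=peak, peep_level=9.0)


class TestProfiles:
    def test_table_thresholds(self):
        p = builtin_profiles()
        assert p["tolerant"].tdi_max_pct == 110 and p["strict"].tdi_max_pct == 110
        assert p["tolerant"].snr_min_pct == 140 and p["strict"].snr_min_pct == 175
        assert p["tolerant"].aub_max_pct == 40 and p["strict"].aub_max_pct == 30
        assert p["tolerant"].bell_error_max_pct == 30 and p["strict"].bell_error_max_pct == 25

    def test_manual_profile_excludes_nothing(self):
        manual = builtin_profiles()["manual"]
        awful = _record(release=50.0, snr=50.0, tdi=100.0, aub_frac=0.9, bell=90.0)
        v = apply_profile(awful, manual)
        assert v.included and not v.failed_criteria

    def test_all_metrics_inside_tolerant_bounds_included(self):
        rec = _record(release=1.2, snr=150.0, tdi=300.0, aub_frac=0.20, bell=10.0)
        assert apply_profile(rec, builtin_profiles()["tolerant"]).included

    def test_snr_150_fails_strict_only(self):
        rec = _record(snr=150.0)
        assert apply_profile(rec, builtin_profiles()["tolerant"]).included
        v = apply_profile(rec, builtin_profiles()["strict"])
        assert not v.included and v.failed_criteria == frozenset({"snr"})

    def test_values_exactly_at_cutoffs_are_kept(self):
        rec = _record(release=2.0, snr=140.0, tdi=110.0, aub_frac=0.40, bell=30.0)
        assert apply_profile(rec, builtin_profiles()["tolerant"]).included

    def test_missing_morphology_excludes(self):
        rec = _record(release=None)
        v = apply_profile(rec, builtin_profiles()["tolerant"])
        assert "pocc_morphology" in v.failed_criteria

    @pytest.mark.parametrize("seed", range(20))
    def test_strict_inclusion_implies_tolerant_inclusion(self, seed):
        rng = np.random.default_rng(seed)
        rec = _record(
            release=float(rng.uniform(0.3, 5)), snr=float(rng.uniform(50, 400)),
            tdi=float(rng.uniform(50, 600)), aub_frac=float(rng.uniform(0, 0.8)),
            bell=float(rng.uniform(0, 60)),
        )
        p = builtin_profiles()
        if apply_profile(rec, p["strict"]).included:
            assert apply_profile(rec, p["tolerant"]).included


class TestSnr:
    def test_ratio(self):
        peak = SEAdiPeak(
            bounds=PeakBounds(1, 2, 3), peak_value=2.8, baseline_at_peak=2.0
        )
        assert compute_snr_pct(peak) == pytest.approx(140.0)

    def test_peak_equal_to_baseline_is_100_and_excluded(self):
        rec = _record(snr=100.0)
        for prof in ("tolerant", "strict"):
            assert "snr" in apply_profile(rec, builtin_profiles()[prof]).failed_criteria

    def test_nonpositive_baseline_is_quality_error(self):
        peak = SEAdiPeak(bounds=PeakBounds(1, 2, 3), peak_value=1.0, baseline_at_peak=0.0)
        with pytest.raises(QualityError):
            compute_snr_pct(peak)


class TestTdi:
    def _peaky_env(self, spacing, dur=20.0, rate=100.0, sigma=0.08):
        t = np.arange(int(dur * rate)) / rate
        x = np.zeros(t.size)
        for c in np.arange(1.0, dur - 1.0, spacing):
            x += np.exp(-((t - c) ** 2) / (2 * sigma**2))
        return _env(0.5 + x, rate=rate)

    def test_cardiac_spaced_peaks_flagged(self):
        qrs = QrsEventSeries(event_times=np.arange(0, 20, 0.8), median_rr=0.8)
        env = self._peaky_env(0.8)
        ratio = compute_tdi_ratio(env, _flat_base(env.n, 0.6), qrs, centred_on=10.0)
        assert ratio == pytest.approx(100.0, abs=3.0)
        assert ratio < 110.0

    def test_respiratory_spacing_passes(self):
        qrs = QrsEventSeries(event_times=np.arange(0, 20, 0.8), median_rr=0.8)
        env = self._peaky_env(4.0)
        ratio = compute_tdi_ratio(env, _flat_base(env.n, 0.6), qrs, centred_on=10.0)
        assert ratio == pytest.approx(500.0, rel=0.05)

    def test_too_few_peaks_unevaluable(self):
        qrs = QrsEventSeries(event_times=np.arange(0, 20, 0.8), median_rr=0.8)
        env = self._peaky_env(15.0)
        assert compute_tdi_ratio(env, _flat_base(env.n, 0.6), qrs, centred_on=10.0) is None


def _grid_best_gaussian_error(t, y, auc_tot, dt):
    """Independent oracle mirroring the declared procedure: dense grid
    search for the least-squares-best Gaussian over (a, mu, sigma), then
    the integrated absolute residual of that fit."""
    best_sse, best_err = np.inf, np.inf
    span = t[-1] - t[0]
    for a in np.linspace(0.1, 1.5, 29) * y.max():
        for mu in np.linspace(t[0], t[-1], 41):
            for sig in np.linspace(span / 40, span, 41):
                resid = y - a * np.exp(-((t - mu) ** 2) / (2 * sig**2))
                sse = float(resid @ resid)
                if sse < best_sse:
                    best_sse = sse
                    best_err = float(np.trapezoid(np.abs(resid), dx=dt))
    return 100.0 * best_err / auc_tot


class TestBellError:
    def test_exact_gaussian_self_fit(self):
        rate = 200.0
        t = np.arange(int(10 * rate)) / rate
        x = 1.0 + 5.0 * np.exp(-((t - 5) ** 2) / (2 * 0.4**2))
        env = _env(x, rate=rate)
        base = _flat_base(t.size, 1.0, rate=rate)
        b = PeakBounds(onset_time=3.5, peak_time=5.0, offset_time=6.5)
        peak = SEAdiPeak(bounds=b, peak_value=6.0, baseline_at_peak=1.0)
        from nmcdi import compute_etp

        peak = compute_etp(env, base, peak)
        assert compute_bell_error_pct(env, base, peak) < 1.0

    def test_square_pulse_matches_grid_oracle_and_exceeds_10pct(self):
        rate = 100.0
        t = np.arange(int(10 * rate)) / rate
        h, w = 4.0, 1.2
        x = np.where(np.abs(t - 5.0) < w / 2, h, 0.0) + 0.01
        env = _env(x, rate=rate)
        base = _flat_base(t.size, 0.005, rate=rate)
        b = PeakBounds(onset_time=5.0 - w / 2 - 0.05, peak_time=5.0, offset_time=5.0 + w / 2 + 0.05)
        from nmcdi import compute_etp

        peak = compute_etp(env, base, SEAdiPeak(bounds=b, peak_value=h, baseline_at_peak=0.005))
        ours = compute_bell_error_pct(env, base, peak)
        i0, i1 = env.index_at(b.onset_time), env.index_at(b.offset_time)
        oracle = _grid_best_gaussian_error(
            t[i0 : i1 + 1], x[i0 : i1 + 1] - 0.005, peak.auc_tot, 1.0 / rate
        )
        assert ours > 10.0
        assert ours == pytest.approx(oracle, rel=0.15)


class TestSummarise:
    def test_counts_and_fractions(self):
        recs = []
        for k in range(10):
            r = _record(snr=100.0 if k < 4 else 200.0)
            for name, prof in builtin_profiles().items():
                r.verdicts[name] = apply_profile(r, prof)
            recs.append(r)
        table = summarise_exclusions(recs, "tolerant")
        snr_row = table[table.criterion == "snr"].iloc[0]
        assert snr_row["count"] == 4 and snr_row["fraction"] == pytest.approx(0.4)
        inc_row = table[table.criterion == "included"].iloc[0]
        assert inc_row["count"] == 6
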