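"""Spike detection, complex-ACF flagging, bound assignment, cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from memprobe.simulate import IntensityTrace
from memprobe.correlate import CorrelationCurve
from memprobe.fcsmodels import FcsModelSpec, FcsFit, model_eval
from memprobe.classify import (detect_spikes, flag_complex_acf, assign_bound,
                               summarize_cohort, MeasurementReport, SpikeReport,
                               classification_bounds)


def _baseline_trace(seed=0, n=4000, mean=100.0):
    rng = np.random.default_rng(seed)
    return rng.poisson(mean, n).astype(float)


def _spiked(counts, start, length, amplitude):
    x = counts.copy()
    x[start:start + length] += amplitude
    return x


def _spike_report(counts, **kw):
    return detect_spikes(IntensityTrace(counts, 5e-3), window=len(counts) * 5e-3, **kw)


class TestDetectSpikes:
    def test_single_rectangular_transit_counts_once(self):
        base = _baseline_trace()
        rep0 = _spike_report(base)
        amp = 10.0 * max(rep0.baseline_range, 1.0)
        rep = _spike_report(_spiked(base, 2000, 40, amp))
        assert rep.n_spikes == 1
        assert 1950 <= rep.spike_indices[0] <= 2005

    def test_subthreshold_transit_ignored(self):
        base = _baseline_trace()
        rep0 = _spike_report(base)
        rep = _spike_report(_spiked(base, 2000, 40, 2.0 * rep0.baseline_range))
        assert rep.n_spikes == 0

    def test_two_separated_transits_count_twice(self):
        base = _baseline_trace()
        amp = 12.0 * _spike_report(base).baseline_range
        x = _spiked(_spiked(base, 1000, 30, amp), 3000, 30, amp)
        assert _spike_report(x).n_spikes == 2

    def test_threshold_invariant_reported(self):
        rep = _spike_report(_baseline_trace())
        assert rep.threshold == pytest.approx(
            rep.baseline_mean + rep.multiplier * rep.baseline_range)

    def test_scale_invariance(self):
        base = _baseline_trace(3)
        amp = 10.0 * _spike_report(base).baseline_range
        x = _spiked(base, 2000, 40, amp)
        a = _spike_report(x)
        b = _spike_report(x * 37.0)
        assert a.n_spikes == b.n_spikes
        assert np.array_equal(a.spike_indices, b.spike_indices)

    @given(st.floats(min_value=5.0, max_value=20.0))
    def test_raising_multiplier_never_adds_spikes(self, mult):
        base = _baseline_trace(5)
        x = _spiked(base, 2000, 40, 8.0 * _spike_report(base).baseline_range)
        lo = _spike_report(x, multiplier=5.0).n_spikes
        hi = _spike_report(x, multiplier=mult).n_spikes
        assert hi <= lo

    def test_window_validation(self):
        tr = IntensityTrace(np.ones(100), 1e-3)
        with pytest.raises(ValueError):
            detect_spikes(tr, window=1.0)


class TestComplexFlag:
    def _curve_and_fit(self, distortion=0.0):
        spec = FcsModelSpec("2D", 2, False)
        params = FcsFit(N=2.0, tau_d1=5e-2, F1=0.5, tau_d2=5e-4)
        lags = np.geomspace(1e-5, 15.0, 260)
        g = model_eval(spec, params, lags)
        rng = np.random.default_rng(2)
        g = g + rng.normal(0, 2e-4, g.shape)
        if distortion:
            # narrow hump centred near 3 s lag, well inside the flag window
            g = g + distortion * np.exp(-(((np.log10(lags) - 0.5) / 0.4) ** 2))
        from memprobe.fcsmodels import fit_curve
        curve = CorrelationCurve(lags, g)
        return curve, fit_curve(curve, spec, bounds=classification_bounds(curve))

    def test_clean_curve_not_flagged(self):
        curve, fit = self._curve_and_fit()
        assert flag_complex_acf(curve, fit) is False

    def test_long_lag_hump_flagged(self):
        curve, fit = self._curve_and_fit(distortion=0.02)
        assert flag_complex_acf(curve, fit) is True

    def test_curve_must_cover_windows(self):
        spec = FcsModelSpec("2D", 1, False)
        params = FcsFit(N=1.0, tau_d1=1e-3)
        lags = np.geomspace(1e-5, 0.5, 100)
        curve = CorrelationCurve(lags, model_eval(spec, params, lags))
        fit = FcsFit(N=1.0, tau_d1=1e-3, model=spec)
        with pytest.raises(ValueError, match="cover"):
            flag_complex_acf(curve, fit)


class TestAssignBound:
    def test_slow_fraction_is_bound(self):
        spec = FcsModelSpec("2D", 2, False)
        fit = FcsFit(N=1.0, tau_d1=5e-2, F1=0.45, tau_d2=4e-4, model=spec)
        b = assign_bound(fit)
        assert b.bound1 and not b.bound2
        assert b.bound_fraction == pytest.approx(0.45)

    def test_both_fast_gives_zero(self):
        spec = FcsModelSpec("2D", 2, False)
        fit = FcsFit(N=1.0, tau_d1=8e-4, F1=0.5, tau_d2=2e-4, model=spec)
        assert assign_bound(fit).bound_fraction == 0.0

    def test_both_slow_gives_one(self):
        spec = FcsModelSpec("2D", 2, False)
        fit = FcsFit(N=1.0, tau_d1=5e-2, F1=0.3, tau_d2=5e-3, model=spec)
        assert assign_bound(fit).bound_fraction == 1.0

    def test_single_component(self):
        spec = FcsModelSpec("2D", 1, False)
        fit = FcsFit(N=1.0, tau_d1=5e-2, model=spec)
        assert assign_bound(fit).bound_fraction == 1.0

    def test_requires_successful_fit(self):
        fit = FcsFit(N=1.0, tau_d1=5e-2, success=False)
        with pytest.raises(ValueError):
            assign_bound(fit)


def _report(trace_id, n_spikes, complex_acf):
    spike = SpikeReport(n_spikes=n_spikes,
                        spike_indices=np.arange(n_spikes),
                        baseline_mean=10.0, baseline_range=2.0,
                        threshold=20.0, window=20.0)
    return MeasurementReport(trace_id=trace_id, spike=spike,
                             complex_acf=complex_acf)


class TestCohortSummary:
    def test_full_overlap(self):
        reps = [_report(f"t{i}", 1, True) for i in range(3)]
        reps += [_report(f"u{i}", 0, False) for i in range(7)]
        s = summarize_cohort(reps)
        assert s.overlap == (3, 0, 0, 7)
        assert s.pct_spiked == pytest.approx(30.0)
        assert s.pct_complex == pytest.approx(30.0)

    def test_disjoint_sets_same_marginals(self):
        reps = [_report(f"s{i}", 1, False) for i in range(3)]
        reps += [_report(f"c{i}", 0, True) for i in range(3)]
        reps += [_report(f"n{i}", 0, False) for i in range(4)]
        s = summarize_cohort(reps)
        assert s.overlap == (0, 3, 3, 4)

    def test_marginals_conserved(self):
        rng = np.random.default_rng(0)
        reps = [_report(f"r{i}", int(rng.integers(0, 3)), bool(rng.integers(0, 2)))
                for i in range(25)]
        s = summarize_cohort(reps)
        assert sum(s.overlap) == s.n_traces == 25
        assert s.pct_spiked == pytest.approx(
            100 * (s.n_spiked_and_complex + s.n_spiked_only) / 25)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_bound_requires_successful_fit(self):
        from memprobe.classify import BoundResult
        spike = SpikeReport(0, np.array([]), 1.0, 1.0, 6.0, 20.0)
        bad_fit = FcsFit(N=1.0, tau_d1=1e-2, success=False)
        with pytest.raises(ValueError):
            MeasurementReport("x", spike, False, fit=bad_fit,
                              bound=BoundResult(True, None, 1.0, 1e-3))
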