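"""Model evaluation and fitting tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from memprobe import fixtures
from memprobe.correlate import CorrelationCurve, segment_stderr
from memprobe.fcsmodels import FcsModelSpec, FcsFit, model_eval, fit_curve, tau_histogram

LAGS = np.geomspace(1e-6, 10.0, 160)


class TestModelEval:
    def test_two_component_arithmetic(self):
        # at lag τ with τ_D1=10τ, τ_D2=0.1τ, F1=0.5: 0.5/1.1 + 0.5/11 = 0.5
        spec = FcsModelSpec("2D", 2, False)
        p = FcsFit(N=1.0, tau_d1=10.0, F1=0.5, tau_d2=0.1)
        assert model_eval(spec, p, [1.0])[0] == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_mixture_equals_one_component(self):
        two = FcsModelSpec("3D", 2, False, K=5.0)
        one = FcsModelSpec("3D", 1, False, K=5.0)
        p2 = FcsFit(N=2.0, tau_d1=1e-3, F1=1.0, tau_d2=1e-5, offset=0.01)
        p1 = FcsFit(N=2.0, tau_d1=1e-3, offset=0.01)
        np.testing.assert_allclose(model_eval(two, p2, LAGS),
                                   model_eval(one, p1, LAGS), rtol=1e-14)

    def test_limits(self):
        spec = FcsModelSpec("2D", 1, False)
        p = FcsFit(N=4.0, tau_d1=1e-3, offset=0.02)
        assert model_eval(spec, p, [1e9])[0] == pytest.approx(0.02, abs=1e-8)
        assert model_eval(spec, p, [0.0])[0] == pytest.approx(0.02 + 0.25)

    def test_triplet_amplitude_preserving(self):
        spec = FcsModelSpec("2D", 1, True)
        p = FcsFit(N=1.0, tau_d1=1.0, F_trip=0.3, tau_trip=1e-5)
        # T(0) = 1/(1-F_trip): amplitude raised above 1/N
        assert model_eval(spec, p, [0.0])[0] == pytest.approx(1 / 0.7)
        # T(τ >> τ_trip) -> 1
        assert model_eval(spec, p, [1e-2])[0] == pytest.approx(1 / 1.01, rel=1e-6)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            model_eval(FcsModelSpec("2D", 1, False), FcsFit(N=1, tau_d1=1), [-1.0])

    @given(st.floats(min_value=1e-5, max_value=1e2),
           st.floats(min_value=1e-5, max_value=1e2))
    def test_monotone_decreasing_without_offset(self, tau1, tau2):
        spec = FcsModelSpec("3D", 2, False, K=5.0)
        p = FcsFit(N=1.5, tau_d1=max(tau1, tau2), F1=0.4,
                   tau_d2=min(tau1, tau2), offset=0.0)
        g = model_eval(spec, p, LAGS)
        assert np.all(np.diff(g) < 0)


@pytest.mark.parametrize("spec,params", [
    (FcsModelSpec("2D", 1, False),
     FcsFit(N=3.0, tau_d1=5e-3, offset=1e-3)),
    (FcsModelSpec("2D", 2, False),
     FcsFit(N=2.5, tau_d1=5e-2, F1=0.6, tau_d2=5e-4, offset=-2e-3)),
    (FcsModelSpec("3D", 1, True, K=5.0),
     FcsFit(N=1.8, tau_d1=5e-4, F_trip=0.15, tau_trip=4e-6, offset=0.0)),
    (FcsModelSpec("3D", 2, False, K=4.0),
     FcsFit(N=4.0, tau_d1=2e-2, F1=0.35, tau_d2=3e-4, offset=5e-4)),
])
def test_noise_free_fit_recovers_parameters(spec, params):
    """Self-consistency: fitting an exact model curve returns its parameters."""
    lags = np.geomspace(2e-6, 20.0, 300)
    curve = CorrelationCurve(lags, model_eval(spec, params, lags))
    fit = fit_curve(curve, spec)
    assert fit.success
    assert fit.N == pytest.approx(params.N, rel=1e-6)
    assert fit.tau_d1 == pytest.approx(params.tau_d1, rel=1e-6)
    assert fit.offset == pytest.approx(params.offset, abs=1e-9)
    if spec.n_components == 2:
        assert fit.F1 == pytest.approx(params.F1, rel=1e-6)
        assert fit.tau_d2 == pytest.approx(params.tau_d2, rel=1e-6)
    if spec.triplet:
        assert fit.F_trip == pytest.approx(params.F_trip, rel=1e-4)
        assert fit.tau_trip == pytest.approx(params.tau_trip, rel=1e-4)


class TestFitBehaviour:
    def test_component_relabeling(self):
        """Components are always ordered slow-first regardless of the basin."""
        spec = FcsModelSpec("2D", 2, False)
        params = FcsFit(N=2.0, tau_d1=1e-2, F1=0.3, tau_d2=2e-4)
        lags = np.geomspace(1e-5, 1.0, 200)
        curve = CorrelationCurve(lags, model_eval(spec, params, lags))
        fit = fit_curve(curve, spec)
        assert fit.tau_d1 >= fit.tau_d2
        assert fit.F1 == pytest.approx(0.3, rel=1e-4)

    def test_too_few_lags_rejected(self):
        spec = FcsModelSpec("2D", 2, True)
        curve = CorrelationCurve(np.geomspace(1e-5, 1e-3, 6), np.linspace(1, 0.5, 6))
        with pytest.raises(ValueError):
            fit_curve(curve, spec)

    def test_weighted_fit_uses_stderr(self):
        spec = FcsModelSpec("2D", 1, False)
        params = FcsFit(N=2.0, tau_d1=1e-3)
        lags = np.geomspace(1e-5, 1.0, 100)
        g = model_eval(spec, params, lags)
        rng = np.random.default_rng(3)
        se = np.full_like(g, 1e-3)
        noisy = g + rng.normal(0, 1e-3, g.shape)
        fit = fit_curve(CorrelationCurve(lags, noisy, stderr=se), spec)
        assert fit.success
        assert fit.redchi == pytest.approx(1.0, abs=0.5)

    def test_init_is_respected(self):
        spec = FcsModelSpec("2D", 1, False)
        params = FcsFit(N=2.0, tau_d1=1e-3)
        lags = np.geomspace(1e-5, 1.0, 80)
        curve = CorrelationCurve(lags, model_eval(spec, params, lags))
        fit = fit_curve(curve, spec, init=FcsFit(N=1.0, tau_d1=5e-3))
        assert fit.tau_d1 == pytest.approx(1e-3, rel=1e-6)


class TestTauHistogram:
    def test_empty(self):
        assert np.array_equal(tau_histogram([], [0, 1, 2]), [0, 0])

    def test_direct_counting_with_open_top_bin(self):
        vals = [5e-3, 40e-3, 400e-3]
        counts = tau_histogram(vals, [0.0, 30e-3, np.inf])
        assert np.array_equal(counts, [1, 2])

    def test_refining_a_bin_conserves_its_count(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 0.2, 50)
        coarse = tau_histogram(vals, [0.0, 30e-3, np.inf])
        fine = tau_histogram(vals, [30e-3, 60e-3, 0.1, np.inf])
        assert fine.sum() == coarse[1]

    def test_failed_fits_skipped(self):
        good = FcsFit(N=1.0, tau_d1=0.05)
        bad = FcsFit(N=1.0, tau_d1=0.05, success=False)
        assert tau_histogram([good, bad], [0.0, 1.0]).sum() == 1

    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            tau_histogram([1.0], [0.0, 0.0, 1.0])


class TestTripletRecovery:
    def test_blinking_parameters_recovered(self):
        """Simulated µs blinking is recovered from weighted fits (median of 3)."""
        from memprobe.simulate import (SpeciesSpec, SimulationConfig,
                                       simulate_trace, tau_d_to_diffusion)
        V = fixtures.VOLUME
        res = []
        for s in range(3):
            sp = SpeciesSpec("m", 78, tau_d_to_diffusion(5e-4, V.w0), 1e5, "3D",
                             triplet_fraction=0.2, triplet_tau=5e-6)
            cfg = SimulationConfig(V, (sp,), (1.125, 1.125, 3.75), 2e-6, 4.0,
                                   500.0, 900 + s)
            tr = simulate_trace(cfg)
            c = segment_stderr(tr, m=16, n_segments=10).restrict(0, 0.05)
            f = fit_curve(c, FcsModelSpec("3D", 1, True, K=5.0))
            res.append((f.F_trip, f.tau_trip))
        arr = np.array(res)
        assert abs(np.median(arr[:, 0]) - 0.2) < 0.05
        assert abs(np.median(arr[:, 1]) - 5e-6) < 2.5e-6


class TestResidualRandomness:
    def test_runs_of_signs_on_single_species_fits(self, solution_fits):
        """A correct model leaves no systematic sign structure in residuals.

        Residuals at neighbouring multitau lags share data and are
        correlated over roughly an octave (16 lags); the runs test is
        applied to every 12th lag, and a systematic model mismatch would
        drive p to zero on every seed.
        """
        from statsmodels.sandbox.stats.runs import runstest_1samp
        n_pass = 0
        for d in solution_fits:
            r = d["fit"].residuals[::12]
            _, p = runstest_1samp(np.sign(r), cutoff=0, correction=False)
            n_pass += p > 0.05
        assert n_pass >= 8
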