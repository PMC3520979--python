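"""Shared fixtures.

The expensive Brownian-dynamics simulations are session-scoped and shared
between the unit/property tests and the acceptance suite, so each study
condition is simulated exactly once per test run.  All seeds are fixed.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from memprobe import fixtures
from memprobe.simulate import simulate_trace, expected_occupancy
from memprobe.correlate import autocorrelate_multitau
from memprobe.fcsmodels import FcsModelSpec, fit_curve
from memprobe.classify import (classify_measurement, detect_spikes,
                               flag_complex_acf, classification_bounds)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MODEL_3D1P = FcsModelSpec("3D", 1, False, K=fixtures.VOLUME.K)
MODEL_2D2P = FcsModelSpec("2D", 2, False)


@pytest.fixture(scope="session")
def solution_fits():
    """10 single-species solution measurements (τ_D = 0.5 ms), fitted 3D 1P."""
    out = []
    for s in range(10):
        cfg = fixtures.solution_config(seed=1300 + s)
        curve = autocorrelate_multitau(simulate_trace(cfg), m=16)
        fit = fit_curve(curve.restrict(0, 1.0), MODEL_3D1P)
        out.append({"config": cfg, "fit": fit,
                    "expected_N": expected_occupancy(cfg, "solution_monomer")})
    return out


@pytest.fixture(scope="session")
def twocomp_fits():
    """10 equal-brightness two-component membrane measurements, fitted 2D 2P."""
    out = []
    for s in range(10):
        cfg = fixtures.two_component_config(seed=1400 + s)
        curve = autocorrelate_multitau(simulate_trace(cfg), m=16)
        out.append(fit_curve(curve, MODEL_2D2P))
    return out


@pytest.fixture(scope="session")
def bias_fits():
    """20 mixtures with the slow species 3× brighter (q² bias probe)."""
    out = []
    for s in range(20):
        cfg = fixtures.two_component_config(seed=1500 + s, brightness_ratio=3.0)
        curve = autocorrelate_multitau(simulate_trace(cfg), m=16)
        out.append(fit_curve(curve, MODEL_2D2P))
    return out


@pytest.fixture(scope="session")
def spike_counts():
    """Spike counts for 20 aggregate-containing and 20 monomer-only traces."""
    agg, mono = [], []
    for s in range(20):
        tr = simulate_trace(fixtures.aggregate_config(seed=1600 + s)).rebin(5)
        agg.append(detect_spikes(tr).n_spikes)
        tr = simulate_trace(fixtures.membrane_monomer_config(
            seed=1600 + s, bin_width=1e-3)).rebin(5)
        mono.append(detect_spikes(tr).n_spikes)
    return np.array(agg), np.array(mono)


@pytest.fixture(scope="session")
def complex_flags():
    """Complex-ACF flags for 20 bleaching-aggregate and 20 monomer traces."""
    def flag(cfg):
        curve = autocorrelate_multitau(simulate_trace(cfg), m=16)
        fit = fit_curve(curve, MODEL_2D2P, bounds=classification_bounds(curve))
        return flag_complex_acf(curve, fit)

    bleach = [flag(fixtures.bleaching_aggregate_config(seed=1700 + s))
              for s in range(20)]
    mono = [flag(fixtures.membrane_monomer_config(seed=1700 + s, duration=60.0))
            for s in range(20)]
    return np.array(bleach), np.array(mono)


@pytest.fixture(scope="session")
def cohort_reports():
    """Fully classified 20-trace good- and poor-binder cohorts."""
    out = {}
    for kind in ("good", "poor"):
        reps = []
        for s in range(20):
            tr = simulate_trace(fixtures.binder_cohort_config(kind, seed=1800 + s))
            reps.append(classify_measurement(tr, MODEL_2D2P,
                                             trace_id=f"{kind}_{s}"))
        out[kind] = reps
    return out
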