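"""Reference synthetic measurement conditions.

These configurations encode the physical regimes the analysis is designed
for, with one fixed set of instrument-like parameters:

* detection volume w0 = 0.25 µm, wz = 1.25 µm (K = 5) — a typical
  visible-light confocal calibration;
* monomer brightness 30 kcounts/s per molecule at the volume center and a
  500 counts/s uniform background — realistic for a TMR-labelled peptide
  at moderate excitation;
* solution probe τ_D = 0.5 ms (3D), membrane-bound probe τ_D in the
  1–100 ms range (2D), unbound membrane-phase probe in the hundreds of µs;
* aggregates 50× brighter than the monomer: rare slow diffusers
  (τ_D ≥ 100 ms at ~0.05 occupancy, producing intensity spikes) or
  immobile bleaching particles (distorting the ACF at second-scale lags);
* 20-s measurements (the spike-counting window) with 60-s traces where
  two-component fitting accuracy is the point.

Box sizes trade boundary fidelity against particle count: periodic
wrap-around re-entry happens on the timescale (2·half)²/4D, which must sit
far beyond the lags being interpreted.  Solution (3D) fits therefore use a
wider lateral box than the minimum.

Every factory takes a ``seed`` so cohorts of independent measurements are
generated by seed offsets.
"""

from __future__ import annotations

import math

from .simulate import (DetectionVolume, SpeciesSpec, SimulationConfig,
                       tau_d_to_diffusion)

__all__ = [
    "VOLUME",
    "MONOMER_BRIGHTNESS",
    "BACKGROUND",
    "AGGREGATE_BRIGHTNESS_RATIO",
    "SPIKE_DETECTION_BIN",
    "solution_config",
    "membrane_monomer_config",
    "membrane_mixture_config",
    "aggregate_config",
    "bleaching_aggregate_config",
    "two_component_config",
    "binder_cohort_config",
]

VOLUME = DetectionVolume(w0=0.25, wz=1.25)
MONOMER_BRIGHTNESS = 30_000.0  # counts/s per molecule at volume center
BACKGROUND = 500.0             # counts/s
AGGREGATE_BRIGHTNESS_RATIO = 50.0
#: intensity-trace bin width (s) at which spike counting operates; traces
#: simulated at finer bins are rebinned to this scale first.
SPIKE_DETECTION_BIN = 5e-3

_LATERAL_HALF = 3 * VOLUME.w0       # minimum box half-width: 0.75 µm
_AXIAL_HALF = 3 * VOLUME.wz         # 3.75 µm
_SOLUTION_HALF = 4.5 * VOLUME.w0    # 1.125 µm; see module docstring
# box in which 2 aggregate particles give exactly 0.05 occupancy
_AGGREGATE_HALF = math.sqrt(2 * VOLUME.effective_area / 0.05) / 2.0


def _n_for_occupancy(occupancy: float, half: float, dimensionality: str) -> int:
    if dimensionality == "3D":
        ratio = VOLUME.effective_volume / (4 * half * half * 2 * _AXIAL_HALF)
    else:
        ratio = VOLUME.effective_area / (4 * half * half)
    return max(1, round(occupancy / ratio))


def solution_config(seed: int, tau_d: float = 5e-4, occupancy: float = 2.0,
                    duration: float = 20.0, bin_width: float = 2e-5,
                    triplet_fraction: float = 0.0, triplet_tau: float = 0.0,
                    ) -> SimulationConfig:
    """Freely diffusing labelled probe in solution (single 3D species)."""
    n = _n_for_occupancy(occupancy, _SOLUTION_HALF, "3D")
    sp = SpeciesSpec("solution_monomer", n, tau_d_to_diffusion(tau_d, VOLUME.w0),
                     MONOMER_BRIGHTNESS, "3D",
                     triplet_fraction=triplet_fraction, triplet_tau=triplet_tau)
    return SimulationConfig(VOLUME, (sp,),
                            (_SOLUTION_HALF, _SOLUTION_HALF, _AXIAL_HALF),
                            bin_width, duration, BACKGROUND, seed)


def membrane_monomer_config(seed: int, tau_d: float = 5e-3, occupancy: float = 2.0,
                            duration: float = 20.0, bin_width: float = 2e-4,
                            half: float = _AGGREGATE_HALF) -> SimulationConfig:
    """Membrane-bound probe only (single slow 2D species, no aggregates)."""
    n = _n_for_occupancy(occupancy, half, "2D")
    sp = SpeciesSpec("membrane_monomer", n, tau_d_to_diffusion(tau_d, VOLUME.w0),
                     MONOMER_BRIGHTNESS, "2D")
    return SimulationConfig(VOLUME, (sp,), (half, half, _AXIAL_HALF),
                            bin_width, duration, BACKGROUND, seed)


def membrane_mixture_config(seed: int, tau_d_slow: float = 0.05,
                            tau_d_fast: float = 5e-4, f_slow: float = 0.5,
                            occupancy_total: float = 4.0,
                            duration: float = 20.0, bin_width: float = 2e-5,
                            half: float = _LATERAL_HALF,
                            extra_species: tuple = ()) -> SimulationConfig:
    """Standard membrane measurement: bound (slow) + unbound (fast) probe.

    ``extra_species`` appends aggregate populations on top of the mixture.
    """
    n_slow = _n_for_occupancy(occupancy_total * f_slow, half, "2D")
    n_fast = _n_for_occupancy(occupancy_total * (1.0 - f_slow), half, "2D")
    species = (
        SpeciesSpec("bound_slow", n_slow, tau_d_to_diffusion(tau_d_slow, VOLUME.w0),
                    MONOMER_BRIGHTNESS, "2D"),
        SpeciesSpec("unbound_fast", n_fast, tau_d_to_diffusion(tau_d_fast, VOLUME.w0),
                    MONOMER_BRIGHTNESS, "2D"),
    ) + tuple(extra_species)
    return SimulationConfig(VOLUME, species, (half, half, _AXIAL_HALF),
                            bin_width, duration, BACKGROUND, seed)


def aggregate_config(seed: int, monomer_tau_d: float = 5e-3,
                     aggregate_tau_d: float = 0.1,
                     duration: float = 20.0, bin_width: float = 1e-3,
                     ) -> SimulationConfig:
    """Membrane probe plus rare bright slow aggregates (spiking traces).

    Two aggregate particles at 50× monomer brightness and τ_D = 100 ms in a
    box sized for exactly 0.05 expected occupancy.  The default 1-ms bins
    suit spike counting; ACF work should use a finer ``bin_width``.
    """
    half = _AGGREGATE_HALF
    n_mono = _n_for_occupancy(2.0, half, "2D")
    mono = SpeciesSpec("membrane_monomer", n_mono,
                       tau_d_to_diffusion(monomer_tau_d, VOLUME.w0),
                       MONOMER_BRIGHTNESS, "2D")
    agg = SpeciesSpec("aggregate", 2,
                      tau_d_to_diffusion(aggregate_tau_d, VOLUME.w0),
                      AGGREGATE_BRIGHTNESS_RATIO * MONOMER_BRIGHTNESS, "2D")
    return SimulationConfig(VOLUME, (mono, agg), (half, half, _AXIAL_HALF),
                            bin_width, duration, BACKGROUND, seed)


def bleaching_aggregate_config(seed: int, n_aggregates: int = 12,
                               bleach_rate: float = 0.05,
                               duration: float = 60.0, bin_width: float = 2e-5,
                               ) -> SimulationConfig:
    """Membrane mixture dominated by immobile bright aggregates that bleach.

    Immobile 50×-brightness emitters decay irreversibly during the
    measurement, adding second-scale correlation structure that the normal
    two-component membrane model cannot absorb — the complex-ACF phenotype
    of an aggregation-prone probe whose slow particles dominate the curve.
    """
    agg = SpeciesSpec("immobile_aggregate", n_aggregates, 0.0,
                      AGGREGATE_BRIGHTNESS_RATIO * MONOMER_BRIGHTNESS, "2D",
                      bleach_rate=bleach_rate)
    return membrane_mixture_config(seed, duration=duration, bin_width=bin_width,
                                   extra_species=(agg,))


def two_component_config(seed: int, tau_d_slow: float = 0.05,
                         tau_d_fast: float = 5e-4,
                         f_slow: float = 0.5, occupancy_total: float = 4.0,
                         brightness_ratio: float = 1.0,
                         duration: float = 60.0, bin_width: float = 2e-5,
                         ) -> SimulationConfig:
    """Mixture of slow (bound) and fast (unbound) 2D diffusers for recovery.

    ``f_slow`` is the true number fraction of the slow species;
    ``brightness_ratio`` multiplies the slow species' brightness (used to
    probe the q² mole-fraction bias).
    """
    half = _LATERAL_HALF
    n_slow = _n_for_occupancy(occupancy_total * f_slow, half, "2D")
    n_fast = _n_for_occupancy(occupancy_total * (1.0 - f_slow), half, "2D")
    slow = SpeciesSpec("bound_slow", n_slow,
                       tau_d_to_diffusion(tau_d_slow, VOLUME.w0),
                       brightness_ratio * MONOMER_BRIGHTNESS, "2D")
    fast = SpeciesSpec("unbound_fast", n_fast,
                       tau_d_to_diffusion(tau_d_fast, VOLUME.w0),
                       MONOMER_BRIGHTNESS, "2D")
    return SimulationConfig(VOLUME, (slow, fast), (half, half, _AXIAL_HALF),
                            bin_width, duration, BACKGROUND, seed)


def binder_cohort_config(kind: str, seed: int, duration: float = 60.0,
                         bin_width: float = 2e-5) -> SimulationConfig:
    """One measurement of a 'good' or 'poor' membrane binder.

    Each call is one confocal spot.  A good binder gives a clean
    two-component membrane measurement everywhere: bound fraction 0.5 with
    the slow population at τ_D = 50 ms, no aggregates.  A poor binder has
    bound fraction 0.2, a slower bound population (τ_D = 200 ms), and —
    because aggregation is spatially heterogeneous — a random subset of
    spots additionally contains aggregates: with probability 0.6 a rare
    bright slow diffusing aggregate (intensity spikes) and, independently
    with probability 0.6, a cluster of immobile bleaching aggregates
    (complex ACFs).  The per-spot composition is drawn deterministically
    from ``seed``.
    """
    import numpy as np

    q_agg = AGGREGATE_BRIGHTNESS_RATIO * MONOMER_BRIGHTNESS
    if kind == "good":
        return membrane_mixture_config(seed, tau_d_slow=0.05, f_slow=0.5,
                                       duration=duration, bin_width=bin_width)
    if kind != "poor":
        raise ValueError("kind must be 'good' or 'poor'")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA66)))
    extras = []
    if rng.random() < 0.6:
        extras.append(SpeciesSpec("aggregate", 1,
                                  tau_d_to_diffusion(0.1, VOLUME.w0),
                                  q_agg, "2D"))
    if rng.random() < 0.6:
        extras.append(SpeciesSpec("immobile_aggregate", 8, 0.0, q_agg, "2D",
                                  bleach_rate=0.1))
    return membrane_mixture_config(seed, tau_d_slow=0.2, f_slow=0.2,
                                   duration=duration, bin_width=bin_width,
                                   extra_species=tuple(extras))
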