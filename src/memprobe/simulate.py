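"""Brownian-dynamics photon-trace simulation for confocal FCS.

Particles diffuse in a periodic box and are detected through a 3D Gaussian
observation profile ``W(r) = exp(-2(x²+y²)/w0² - 2z²/wz²)``.  Membrane-bound
species are confined to the focal plane (z = 0, 2D diffusion); solution
species diffuse in 3D.  Each species may blink through a single reversible
dark (triplet) state and may bleach irreversibly.  Detected counts per time
bin are Poisson-distributed around the instantaneous summed emission rate
plus a uniform background, which reproduces photon shot noise.

The diffusion time convention throughout the package is
``tau_D = w0² / (4 D)`` — the mean lateral transit time through the
Gaussian waist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import propagate_block

__all__ = [
    "DetectionVolume",
    "SpeciesSpec",
    "SimulationConfig",
    "IntensityTrace",
    "simulate_trace",
    "expected_occupancy",
    "mean_profile",
    "tau_d_to_diffusion",
    "diffusion_to_tau_d",
]


def tau_d_to_diffusion(tau_d: float, w0: float) -> float:
    """Diffusion coefficient (µm²/s) for a transit time ``tau_d`` (s)."""
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    return w0 * w0 / (4.0 * tau_d)


def diffusion_to_tau_d(D: float, w0: float) -> float:
    """Transit time ``tau_D = w0²/(4D)`` (s) for diffusion coefficient D."""
    if D <= 0:
        raise ValueError("D must be positive")
    return w0 * w0 / (4.0 * D)


@dataclass(frozen=True)
class DetectionVolume:
    """Gaussian confocal observation volume.

    Parameters
    ----------
    w0 : lateral 1/e² radius in µm.
    wz : axial 1/e² radius in µm; must satisfy wz >= w0.
    """

    w0: float = 0.25
    wz: float = 1.25

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")
        if self.wz < self.w0:
            raise ValueError("wz must be >= w0 (structure parameter K >= 1)")

    @property
    def K(self) -> float:
        """Structure parameter wz/w0."""
        return self.wz / self.w0

    @property
    def effective_volume(self) -> float:
        """3D effective volume π^{3/2} w0² wz (µm³)."""
        return math.pi ** 1.5 * self.w0 ** 2 * self.wz

    @property
    def effective_area(self) -> float:
        """2D effective area π w0² (µm²)."""
        return math.pi * self.w0 ** 2


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing fluorescent species.

    brightness is the mean detected count rate (counts/s) for a particle at
    the center of the observation volume in the bright state.
    triplet_fraction is the equilibrium dark-state occupancy; triplet_tau the
    relaxation time of the two-state blinking chain.  bleach_rate > 0 adds an
    irreversible per-particle dark conversion (immobile bleaching aggregates).
    """

    label: str
    n_particles: int
    D: float
    brightness: float
    dimensionality: str = "3D"
    triplet_fraction: float = 0.0
    triplet_tau: float = 0.0
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError("triplet_fraction must be in [0, 1)")
        if self.triplet_fraction > 0 and self.triplet_tau <= 0:
            raise ValueError("triplet_tau must be positive when blinking is on")
        if self.dimensionality not in ("2D", "3D"):
            raise ValueError("dimensionality must be '2D' or '3D'")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic measurement."""

    volume: DetectionVolume
    species: tuple[SpeciesSpec, ...]
    box: tuple[float, float, float]
    bin_width: float
    duration: float
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "box", tuple(float(b) for b in self.box))
        if len(self.box) != 3:
            raise ValueError("box must give three half-widths (µm)")
        if any(b <= 0 for b in self.box):
            raise ValueError("box half-widths must be positive")
        if not (self.duration >= self.bin_width > 0):
            raise ValueError("need duration >= bin_width > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        w0, wz = self.volume.w0, self.volume.wz
        if self.box[0] < 3 * w0 or self.box[1] < 3 * w0:
            raise ValueError("lateral box half-widths must be >= 3*w0")
        if any(s.dimensionality == "3D" for s in self.species) and self.box[2] < 3 * wz:
            raise ValueError("axial box half-width must be >= 3*wz for 3D species")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))


@dataclass
class IntensityTrace:
    """Binned photon counts — the raw FCS observable."""

    counts: np.ndarray
    bin_width: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def duration(self) -> float:
        return len(self.counts) * self.bin_width

    @property
    def times(self) -> np.ndarray:
        """Left edge of each bin (s)."""
        return np.arange(len(self.counts)) * self.bin_width

    def rebin(self, factor: int) -> "IntensityTrace":
        """Sum counts over consecutive groups of ``factor`` bins."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if factor == 1:
            return IntensityTrace(self.counts.copy(), self.bin_width, dict(self.metadata))
        n = (len(self.counts) // factor) * factor
        summed = self.counts[:n].reshape(-1, factor).sum(axis=1)
        meta = dict(self.metadata)
        meta["rebinned_by"] = int(meta.get("rebinned_by", 1)) * factor
        return IntensityTrace(summed, self.bin_width * factor, meta)


def _max_step(species: SpeciesSpec, bin_width: float) -> float:
    return math.sqrt(2.0 * species.D * bin_width)


def simulate_trace(config: SimulationConfig) -> IntensityTrace:
    """Simulate one photon-count trace.

    Per bin, each mobile coordinate advances by a Gaussian step of standard
    deviation sqrt(2 D Δt), positions wrap periodically (minimum-image
    Gaussian mask), blinking follows exact two-state Markov propagation per
    bin, and the bin count is Poisson with mean (Σ rates + background)·Δt.

    Identical config (including seed) gives a bit-identical trace.

    Raises
    ------
    ValueError
        If any species' RMS step exceeds w0/2 — the discretization would
        under-sample the detection profile; use a finer bin_width.
    """
    w0, wz = config.volume.w0, config.volume.wz
    dt = config.bin_width
    for sp in config.species:
        if _max_step(sp, dt) > w0 / 2.0:
            raise ValueError(
                f"species {sp.label!r}: RMS step {_max_step(sp, dt):.4g} µm exceeds "
                f"w0/2 = {w0 / 2:.4g} µm; choose a finer bin_width (or sub-step)"
            )

    n_bins = config.n_bins
    rate = np.zeros(n_bins)  # summed detected rate, counts/s
    children = np.random.SeedSequence(config.seed).spawn(len(config.species) + 1)

    for sp, child in zip(config.species, children):
        if sp.n_particles == 0 or sp.brightness == 0.0:
            continue
        rng = np.random.Generator(np.random.SFC64(child))
        n = sp.n_particles
        hx, hy, hz = config.box
        pos = np.empty((n, 3))
        pos[:, 0] = rng.uniform(-hx, hx, n)
        pos[:, 1] = rng.uniform(-hy, hy, n)
        if sp.dimensionality == "3D":
            pos[:, 2] = rng.uniform(-hz, hz, n)
        else:
            pos[:, 2] = 0.0

        use_trip = sp.triplet_fraction > 0.0
        state = np.zeros(n, dtype=np.int8)
        if use_trip:
            state[rng.random(n) < sp.triplet_fraction] = 1
            decay = 1.0 - math.exp(-dt / sp.triplet_tau)
            p_b2d = sp.triplet_fraction * decay
            p_d2b = (1.0 - sp.triplet_fraction) * decay
        else:
            p_b2d = p_d2b = 0.0
        p_bleach = 1.0 - math.exp(-sp.bleach_rate * dt) if sp.bleach_rate > 0 else 0.0

        sigma = _max_step(sp, dt)
        n_mobile = 3 if sp.dimensionality == "3D" else 2
        half = np.array([hx, hy, hz])
        profile = np.zeros(n_bins)
        dummy2 = np.zeros((1, 1))
        dummy3 = np.zeros((1, 1, 1))
        # chunked bulk RNG keeps memory bounded for long traces
        chunk = max(1, min(n_bins, 4_000_000 // n))
        start = 0
        while start < n_bins:
            k = min(chunk, n_bins - start)
            steps = rng.standard_normal((k, n, n_mobile)) if sigma > 0 else dummy3
            u_trip = rng.random((k, n)) if use_trip else dummy2
            u_bleach = rng.random((k, n)) if p_bleach > 0 else dummy2
            propagate_block(
                pos, state, steps, sigma, n_mobile, u_trip, u_bleach, half,
                1.0 / (w0 * w0), 1.0 / (wz * wz),
                p_b2d, p_d2b, p_bleach, profile[start:start + k],
            )
            start += k
        rate += sp.brightness * profile

    det_rng = np.random.default_rng(children[-1])
    counts = det_rng.poisson((rate + config.background) * dt)
    meta = {
        "seed": config.seed,
        "bin_width": dt,
        "duration": config.duration,
        "species": [sp.label for sp in config.species],
    }
    return IntensityTrace(counts.astype(np.int64), dt, meta)


def expected_occupancy(config: SimulationConfig, species_label: str) -> float:
    """Mean particle number of one species in the effective detection volume.

    ``n · V_eff / V_box`` with V_eff = π^{3/2} w0² wz for 3D species and
    A_eff = π w0² (against the box *area*) for 2D species.  This is the N
    that an ideal FCS amplitude fit recovers for a single dilute species.
    """
    for sp in config.species:
        if sp.label == species_label:
            break
    else:
        raise KeyError(f"no species labelled {species_label!r}")
    hx, hy, hz = config.box
    if sp.dimensionality == "3D":
        return sp.n_particles * config.volume.effective_volume / (8.0 * hx * hy * hz)
    return sp.n_particles * config.volume.effective_area / (4.0 * hx * hy)


def _axis_mean(w: float, half: float) -> float:
    # mean of exp(-2u²/w²) for u uniform on [-half, half]
    return w * math.sqrt(math.pi / 2.0) * math.erf(math.sqrt(2.0) * half / w) / (2.0 * half)


def mean_profile(volume: DetectionVolume, box: Sequence[float], dimensionality: str) -> float:
    """Closed-form box average of the Gaussian detection profile ⟨W⟩.

    Mean detected rate of a species is brightness·(1-triplet_fraction)·n·⟨W⟩.
    """
    hx, hy, hz = box
    m = _axis_mean(volume.w0, hx) * _axis_mean(volume.w0, hy)
    if dimensionality == "3D":
        m *= _axis_mean(volume.wz, hz)
    return m
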