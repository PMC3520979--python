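"""SPR sensorgram quantification and a closed-form Langmuir generator.

Fraction binding is the association-phase response gain — response at the
end of injection minus the response at the start reference (injection start
plus an exclusion window, default 30 s, which skips the bulk refractive-
index jump) — divided by the flow cell's normalized immobilization level.
Fraction bound is the re-baselined response after the dissociation phase
(default 15 min of buffer flow), divided by the same normalization.  The
normalized immobilization of a flow cell is its captured-liposome RU
divided by the mean over all flow cells of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Sensorgram",
    "BindingFractions",
    "normalize_immobilization",
    "fraction_binding",
    "fraction_bound",
    "quantify",
    "simulate_sensorgram",
    "langmuir_response",
]


@dataclass
class Sensorgram:
    """SPR response time series with phase markers (all times in s, RU units)."""

    time: np.ndarray
    response: np.ndarray
    injection_start: float
    injection_end: float
    dissociation_end: float
    immobilization: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must match in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.injection_start < self.injection_end < self.dissociation_end):
            raise ValueError("need injection_start < injection_end < dissociation_end")
        if self.dissociation_end > self.time[-1]:
            raise ValueError("dissociation_end outside the recorded time range")
        if self.immobilization <= 0:
            raise ValueError("immobilization must be positive")

    def at(self, t: float) -> float:
        """Response linearly interpolated at time t."""
        if t < self.time[0] or t > self.time[-1]:
            raise ValueError(f"t={t} outside recorded range")
        return float(np.interp(t, self.time, self.response))

    def baseline(self, pre_window: float = 10.0) -> float:
        """Mean response over the ``pre_window`` seconds before injection."""
        m = (self.time >= self.injection_start - pre_window) & (self.time < self.injection_start)
        if not np.any(m):
            return self.at(max(self.injection_start, self.time[0]))
        return float(self.response[m].mean())


@dataclass
class BindingFractions:
    fraction_binding: float
    fraction_bound: float
    normalized_immobilization: float

    def __post_init__(self) -> None:
        if self.normalized_immobilization <= 0:
            raise ValueError("normalized immobilization must be positive")
        if not (np.isfinite(self.fraction_binding) and np.isfinite(self.fraction_bound)):
            raise ValueError("fractions must be finite")


def normalize_immobilization(immobilizations: Sequence[float]) -> np.ndarray:
    """Each flow cell's immobilization RU divided by the mean over all cells."""
    vals = np.asarray(immobilizations, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one flow cell")
    if np.any(vals <= 0):
        raise ValueError("immobilization levels must be positive")
    return vals / vals.mean()


def fraction_binding(sg: Sensorgram, norm: float, exclusion: float = 30.0) -> float:
    """Association-phase response gain over the normalized immobilization.

    (R(injection_end) − R(injection_start + exclusion)) / norm.  The start
    reference sits ``exclusion`` seconds into the injection so the bulk
    jump at the injection front is excluded.
    """
    if norm <= 0:
        raise ValueError("norm must be positive")
    if not exclusion < sg.injection_end - sg.injection_start:
        raise ValueError("exclusion must be shorter than the injection phase")
    start_ref = sg.at(sg.injection_start + exclusion)
    return (sg.at(sg.injection_end) - start_ref) / norm


def fraction_bound(sg: Sensorgram, norm: float, pre_window: float = 10.0) -> float:
    """Re-baselined response at the end of dissociation over the normalization."""
    if norm <= 0:
        raise ValueError("norm must be positive")
    return (sg.at(sg.dissociation_end) - sg.baseline(pre_window)) / norm


def quantify(sg: Sensorgram, norm: float, exclusion: float = 30.0) -> BindingFractions:
    """Both sensorgram statistics for one flow cell."""
    return BindingFractions(
        fraction_binding=fraction_binding(sg, norm, exclusion),
        fraction_bound=fraction_bound(sg, norm),
        normalized_immobilization=norm,
    )


def langmuir_response(t, kon_c: float, koff: float, rmax: float,
                      injection_start: float, injection_end: float):
    """Noise-free 1:1 Langmuir response at times t (piecewise closed form).

    Association: R(t) = Req (1 − e^{−(konC+koff)(t−t₀)}) with
    Req = Rmax·konC/(konC+koff); dissociation: R(t_end)·e^{−koff(t−t_end)}.
    """
    t = np.asarray(t, dtype=float)
    ktot = kon_c + koff
    req = rmax * kon_c / ktot if ktot > 0 else 0.0
    r = np.zeros_like(t)
    assoc = (t >= injection_start) & (t <= injection_end)
    r[assoc] = req * (1.0 - np.exp(-ktot * (t[assoc] - injection_start)))
    r_end = req * (1.0 - np.exp(-ktot * (injection_end - injection_start)))
    dissoc = t > injection_end
    r[dissoc] = r_end * np.exp(-koff * (t[dissoc] - injection_end))
    return r


def simulate_sensorgram(kon_c: float, koff: float, rmax: float,
                        injection_start: float = 110.0,
                        injection_end: float = 350.0,
                        dissociation_end: float | None = None,
                        immobilization: float = 5000.0,
                        dt: float = 1.0,
                        bulk_jump: float = 0.0,
                        noise_sd: float = 0.0,
                        drift: float = 0.0,
                        seed: int = 0) -> Sensorgram:
    """Synthetic 1:1 Langmuir sensorgram with bulk jump, noise and drift.

    The bulk refractive-index jump adds a square ``bulk_jump`` RU offset
    during the injection only; Gaussian noise (sd in RU) and a linear
    baseline drift (RU/s) are added on top.  Default phase markers mimic a
    typical capture experiment (association starting ~110 s, 240 s
    injection, 15 min dissociation).
    """
    if kon_c < 0 or koff < 0:
        raise ValueError("rates must be >= 0")
    if dissociation_end is None:
        dissociation_end = injection_end + 900.0
    t = np.arange(0.0, dissociation_end + 30.0 + dt / 2, dt)
    r = langmuir_response(t, kon_c, koff, rmax, injection_start, injection_end)
    r = r + bulk_jump * ((t >= injection_start) & (t <= injection_end))
    r = r + drift * t
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    return Sensorgram(t, r, injection_start, injection_end, dissociation_end,
                      immobilization)
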