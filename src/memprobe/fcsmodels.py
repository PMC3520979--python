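"""FCS autocorrelation models and nonlinear fitting.

The fitted model is

    G(τ) = offset + (1/N) · T(τ) · D(τ)

with an amplitude-preserving triplet factor

    T(τ) = (1 − F_trip + F_trip · e^{−τ/τ_trip}) / (1 − F_trip)

(T ≡ 1 with the triplet term disabled) and a diffusion factor that is a
mole-fraction (not brightness-weighted) sum of one or two components:

    2D:  (1 + τ/τ_D)^{-1}
    3D:  (1 + τ/τ_D)^{-1} · (1 + τ/(K² τ_D))^{-1/2}

N is the apparent particle number in the effective detection volume; K the
structure parameter wz/w0, a fixed calibration constant (never fitted —
it is not identifiable jointly with τ_D at realistic noise).  Because the
amplitude weights components by the square of molecular brightness, the
fitted mole fractions are biased toward brighter species: for occupancies
N₁, N₂ and brightnesses q₁, q₂ the apparent fraction of species 2
converges to N₂q₂² / (N₁q₁² + N₂q₂²), so mixtures containing aggregates
overestimate the aggregate fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import lmfit

from .correlate import CorrelationCurve

__all__ = ["FcsModelSpec", "FcsFit", "model_eval", "fit_curve", "tau_histogram"]


@dataclass(frozen=True)
class FcsModelSpec:
    """Which ACF model to evaluate/fit: 2D/3D, 1 or 2 components, ± triplet."""

    dimensionality: str = "2D"
    n_components: int = 2
    triplet: bool = True
    K: float = 5.0

    def __post_init__(self) -> None:
        if self.dimensionality not in ("2D", "3D"):
            raise ValueError("dimensionality must be '2D' or '3D'")
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if self.dimensionality == "3D" and self.K <= 1:
            raise ValueError("K must be > 1 for 3D models")

    @property
    def name(self) -> str:
        t = "1t" if self.triplet else ""
        return f"{self.dimensionality.lower()}{self.n_components}p{t}"

    @property
    def n_free(self) -> int:
        n = 2 + 1  # N, tau_d1, offset
        if self.n_components == 2:
            n += 2  # F1, tau_d2
        if self.triplet:
            n += 2  # F_trip, tau_trip
        return n


@dataclass
class FcsFit:
    """Fitted (or constructed) ACF parameters.

    Convention: component 1 is the slow one (tau_d1 >= tau_d2); F2 = 1 - F1.
    """

    N: float
    tau_d1: float
    F1: float = 1.0
    tau_d2: float = 0.0
    F_trip: float = 0.0
    tau_trip: float = 0.0
    offset: float = 0.0
    stderrs: dict = field(default_factory=dict)
    redchi: float = float("nan")
    residuals: Optional[np.ndarray] = None
    lags: Optional[np.ndarray] = None
    success: bool = True
    flags: tuple = ()
    model: Optional[FcsModelSpec] = None

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not 0.0 <= self.F1 <= 1.0:
            raise ValueError("F1 must be in [0, 1]")
        if not 0.0 <= self.F_trip < 1.0:
            raise ValueError("F_trip must be in [0, 1)")

    @property
    def F2(self) -> float:
        return 1.0 - self.F1


def _diffusion_factor(spec: FcsModelSpec, tau_d: float, lags: np.ndarray) -> np.ndarray:
    x = lags / tau_d
    if spec.dimensionality == "2D":
        return 1.0 / (1.0 + x)
    return 1.0 / ((1.0 + x) * np.sqrt(1.0 + x / (spec.K ** 2)))


def model_eval(spec: FcsModelSpec, params: FcsFit, lags) -> np.ndarray:
    """Evaluate G(τ) on the given lags."""
    lags = np.asarray(lags, dtype=float)
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    if spec.triplet and params.F_trip >= 1.0:
        raise ValueError("F_trip = 1 gives a divergent triplet normalization")
    if spec.triplet and params.F_trip > 0.0:
        T = (1.0 - params.F_trip
             + params.F_trip * np.exp(-lags / params.tau_trip)) / (1.0 - params.F_trip)
    else:
        T = 1.0
    D = _diffusion_factor(spec, params.tau_d1, lags)
    if spec.n_components == 2:
        D = params.F1 * D + (1.0 - params.F1) * _diffusion_factor(spec, params.tau_d2, lags)
    return params.offset + T * D / params.N


def _initial_guess(curve: CorrelationCurve) -> tuple[float, float, float]:
    """(amplitude, tau_half, offset) heuristics from the curve shape."""
    G = curve.G
    lags = curve.lags
    n_tail = max(3, len(G) // 10)
    offset0 = float(np.mean(G[-n_tail:]))
    g0 = float(np.mean(G[: min(3, len(G))]))
    amp = max(g0 - offset0, 1e-9)
    below = np.nonzero(G - offset0 < amp / 2.0)[0]
    tau_half = float(lags[below[0]]) if len(below) else float(lags[len(lags) // 2])
    return amp, tau_half, offset0


def _build_params(spec: FcsModelSpec, amp: float, tau_half: float, offset0: float,
                  lags: np.ndarray, init: Optional[FcsFit],
                  bounds: Optional[dict]) -> lmfit.Parameters:
    lag_min, lag_max = float(lags[0]), float(lags[-1])
    tau_lo, tau_hi = lag_min / 10.0, lag_max * 10.0
    p = lmfit.Parameters()
    p.add("N", value=1.0 / amp, min=1e-8)
    p.add("offset", value=offset0)
    if spec.n_components == 2:
        p.add("F1", value=0.5, min=0.0, max=1.0)
        p.add("tau_d1", value=min(tau_half * 10.0, tau_hi), min=tau_lo, max=tau_hi)
        p.add("tau_d2", value=max(tau_half / 10.0, tau_lo), min=tau_lo, max=tau_hi)
    else:
        p.add("F1", value=1.0, vary=False)
        p.add("tau_d1", value=tau_half, min=tau_lo, max=tau_hi)
        p.add("tau_d2", value=0.0, vary=False)
    if spec.triplet:
        p.add("F_trip", value=0.1, min=0.0, max=0.999)
        # blinking is µs-scale: keep it within two decades of the first lag
        p.add("tau_trip", value=3.0 * lag_min, min=lag_min / 100.0, max=100.0 * lag_min)
    else:
        p.add("F_trip", value=0.0, vary=False)
        p.add("tau_trip", value=0.0, vary=False)
    if init is not None:
        for name, val in (("N", init.N), ("F1", init.F1), ("tau_d1", init.tau_d1),
                          ("tau_d2", init.tau_d2), ("F_trip", init.F_trip),
                          ("tau_trip", init.tau_trip), ("offset", init.offset)):
            if p[name].vary and val is not None:
                lo, hi = p[name].min, p[name].max
                p[name].value = min(max(val, lo if np.isfinite(lo) else val),
                                    hi if np.isfinite(hi) else val)
    if bounds:
        for name, (lo, hi) in bounds.items():
            p[name].min, p[name].max = lo, hi
    return p


def _eval_params(spec: FcsModelSpec, p: lmfit.Parameters, lags: np.ndarray) -> np.ndarray:
    v = p.valuesdict()
    ft = v["F_trip"]
    if spec.triplet and ft > 0:
        T = (1.0 - ft + ft * np.exp(-lags / v["tau_trip"])) / (1.0 - ft)
    else:
        T = 1.0
    D = _diffusion_factor(spec, v["tau_d1"], lags)
    if spec.n_components == 2:
        D = v["F1"] * D + (1.0 - v["F1"]) * _diffusion_factor(spec, v["tau_d2"], lags)
    return v["offset"] + T * D / v["N"]


def fit_curve(curve: CorrelationCurve, spec: FcsModelSpec,
              init: Optional[FcsFit] = None,
              bounds: Optional[dict] = None) -> FcsFit:
    """Weighted least-squares fit of the chosen model to a correlation curve.

    Weights are 1/stderr² where the curve carries positive finite standard
    errors, otherwise uniform.  A small multi-start schedule (three spreads
    of the half-decay initialization) guards against the two-component
    timescale split landing in the wrong basin.  Components are relabeled
    so that tau_d1 >= tau_d2.  Non-convergence is reported as a result with
    ``success=False`` rather than an exception; parameters that end on a
    bound are listed in ``flags``.
    """
    lags = curve.lags
    if len(lags) < 2 * spec.n_free:
        raise ValueError("curve has too few lags for the number of free parameters")
    G = curve.G
    if curve.stderr is not None and np.all(np.isfinite(curve.stderr)) and np.all(curve.stderr > 0):
        weights = 1.0 / curve.stderr
    else:
        weights = np.ones_like(G)

    amp, tau_half, offset0 = _initial_guess(curve)

    best = None
    for spread in (1.0, 0.3, 3.0):
        p = _build_params(spec, amp, tau_half * spread, offset0, lags,
                          init if spread == 1.0 else None, bounds)

        def resid(pars):
            return (_eval_params(spec, pars, lags) - G) * weights

        try:
            res = lmfit.minimize(resid, p, method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.redchi < best.redchi):
            best = res
        if init is not None and spread == 1.0 and best is not None:
            break

    if best is None:
        return FcsFit(N=1.0 / amp, tau_d1=tau_half, offset=offset0,
                      success=False, flags=("no_convergence",), model=spec,
                      lags=lags, residuals=np.full_like(G, np.nan))

    v = best.params.valuesdict()
    err = {k: (best.params[k].stderr if best.params[k].stderr is not None else float("nan"))
           for k in v}
    f1, t1, t2 = v["F1"], v["tau_d1"], v["tau_d2"]
    if spec.n_components == 2 and t2 > t1:
        t1, t2 = t2, t1
        f1 = 1.0 - f1
        err["tau_d1"], err["tau_d2"] = err["tau_d2"], err["tau_d1"]

    flags = []
    for name in ("N", "F1", "tau_d1", "tau_d2", "F_trip", "tau_trip"):
        par = best.params[name]
        if not par.vary:
            continue
        span = (par.max - par.min) if np.isfinite(par.max) and np.isfinite(par.min) else abs(par.value) + 1.0
        if (np.isfinite(par.min) and par.value - par.min < 1e-6 * span) or \
           (np.isfinite(par.max) and par.max - par.value < 1e-6 * span):
            flags.append(f"at_bound:{name}")

    fitted = _eval_params(spec, best.params, lags)
    return FcsFit(
        N=v["N"], tau_d1=t1, F1=f1, tau_d2=t2,
        F_trip=v["F_trip"], tau_trip=v["tau_trip"], offset=v["offset"],
        stderrs=err, redchi=float(best.redchi),
        residuals=G - fitted, lags=lags,
        success=True, flags=tuple(flags), model=spec,
    )


def tau_histogram(fits: Sequence, edges) -> np.ndarray:
    """Counts of slow-component diffusion times per half-open bin.

    ``fits`` may hold FcsFit objects (their tau_d1 is used; failed fits are
    skipped) or bare diffusion times.  ``edges`` are strictly increasing and
    may end in inf.  Re-histogramming one coarse bin at finer edges spanning
    the same interval conserves its total count.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    values = []
    for f in fits:
        if isinstance(f, FcsFit):
            if f.success:
                values.append(f.tau_d1)
        else:
            values.append(float(f))
    if not values:
        return np.zeros(len(edges) - 1, dtype=int)
    values = np.asarray(values)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(len(edges) - 1):
        counts[i] = int(np.sum((values >= edges[i]) & (values < edges[i + 1])))
    return counts
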