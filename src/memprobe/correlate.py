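"""Intensity autocorrelation: direct pair-average oracle and multiple-tau.

Both estimators use symmetric (lag-dependent) normalization,

    G(k·Δt) = ⟨I_t · I_{t+k}⟩ / (⟨I_t⟩_L · ⟨I_{t+k}⟩_R) − 1,

where the left/right means run over the same valid pairs as the product.
The symmetric form tolerates slow drift and bleaching better than a global
mean and makes the multiple-tau level-0 values bit-identical to the direct
estimator at the shared (first 2m) lags; at rebinned levels the two agree
only statistically, because progressive rebinning averages the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .simulate import IntensityTrace

__all__ = [
    "CorrelationCurve",
    "autocorrelate_direct",
    "autocorrelate_multitau",
    "segment_stderr",
]


@dataclass
class CorrelationCurve:
    """Normalized autocorrelation G(τ) on a set of lag times."""

    lags: np.ndarray
    G: np.ndarray
    stderr: Optional[np.ndarray] = None
    n_samples: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise ValueError("lags and G must have the same shape")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.G.shape:
                raise ValueError("stderr must match G in length")
            if np.any(self.stderr < 0):
                raise ValueError("stderr must be >= 0")

    def restrict(self, lo: float, hi: float) -> "CorrelationCurve":
        """Sub-curve with lo <= lag <= hi."""
        m = (self.lags >= lo) & (self.lags <= hi)
        return CorrelationCurve(
            self.lags[m], self.G[m],
            None if self.stderr is None else self.stderr[m],
            None if self.n_samples is None else self.n_samples[m],
        )


def _g_at_lag(x: np.ndarray, k: int) -> float:
    left = x[:-k]
    right = x[k:]
    ml = left.mean()
    mr = right.mean()
    if ml == 0.0 or mr == 0.0:
        raise ValueError("zero-mean segment: normalization undefined")
    return float(np.dot(left, right) / len(left) / (ml * mr) - 1.0)


def autocorrelate_direct(trace: IntensityTrace, max_lag: float) -> CorrelationCurve:
    """Brute-force autocorrelation at every integer lag up to ``max_lag``.

    O(N·K); intended as the validation oracle for the multiple-tau scheme
    and for short traces.  Requires max_lag < duration/2 and a non-zero
    mean trace.
    """
    x = np.asarray(trace.counts, dtype=float)
    dt = trace.bin_width
    if x.mean() == 0.0:
        raise ValueError("trace has zero mean; G is undefined")
    if not max_lag < trace.duration / 2:
        raise ValueError("max_lag must be < duration/2")
    kmax = int(round(max_lag / dt))
    if kmax < 1:
        raise ValueError("max_lag shorter than one bin")
    lags = np.arange(1, kmax + 1) * dt
    G = np.array([_g_at_lag(x, k) for k in range(1, kmax + 1)])
    n = len(x) - np.arange(1, kmax + 1)
    return CorrelationCurve(lags, G, n_samples=n)


def _rebin2(x: np.ndarray) -> np.ndarray:
    n = (len(x) // 2) * 2
    return 0.5 * (x[:n:2] + x[1:n:2])


def autocorrelate_multitau(trace: IntensityTrace, m: int = 16) -> CorrelationCurve:
    """Quasi-logarithmic multiple-tau autocorrelation.

    Level 0 evaluates lags 1..2m on the raw trace (identical arithmetic to
    :func:`autocorrelate_direct`); each further level halves the time
    resolution by pairwise averaging and evaluates lags (m+1)..2m in the
    rebinned units, so lag spacing doubles per octave.  Levels are added
    while the rebinned signal still has at least one pair at the longest
    lag, giving a ladder from Δt out to roughly half the trace length.
    """
    if m < 8 or m % 2 != 0:
        raise ValueError("m must be even and >= 8")
    x = np.asarray(trace.counts, dtype=float)
    if x.mean() == 0.0:
        raise ValueError("trace has zero mean; G is undefined")
    if len(x) < 4 * m:
        raise ValueError("trace too short for one octave (need length >= 4m)")
    dt = trace.bin_width
    lags, G, ns = [], [], []
    for k in range(1, 2 * m + 1):
        lags.append(k * dt)
        G.append(_g_at_lag(x, k))
        ns.append(len(x) - k)
    level_dt = dt
    z = x
    while True:
        z = _rebin2(z)
        level_dt *= 2.0
        if len(z) <= 2 * m:
            break
        for k in range(m + 1, 2 * m + 1):
            if k >= len(z):
                break
            lags.append(k * level_dt)
            G.append(_g_at_lag(z, k))
            ns.append(len(z) - k)
    return CorrelationCurve(np.array(lags), np.array(G), n_samples=np.array(ns))


def segment_stderr(trace: IntensityTrace, m: int = 16, n_segments: int = 10) -> CorrelationCurve:
    """Multiple-tau curve with per-lag standard errors from trace segments.

    The trace is cut into ``n_segments`` equal pieces, each correlated
    separately, and the standard error of the per-segment G is attached.
    Only lags that every segment's ladder reaches are returned, so the
    curve is shorter than the full-trace ladder.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    n = len(trace.counts) // n_segments
    if n < 4 * m:
        raise ValueError("segments too short for one octave; reduce n_segments")
    curves = []
    for i in range(n_segments):
        seg = IntensityTrace(trace.counts[i * n:(i + 1) * n], trace.bin_width)
        curves.append(autocorrelate_multitau(seg, m=m))
    n_lags = min(len(c.lags) for c in curves)
    lags = curves[0].lags[:n_lags]
    stack = np.vstack([c.G[:n_lags] for c in curves])
    G = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n_segments)
    return CorrelationCurve(lags, G, stderr=se)
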