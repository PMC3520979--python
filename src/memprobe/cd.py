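"""Circular-dichroism unit conversion.

Observed ellipticity θ (millidegrees) is converted to mean residue
ellipticity

    [θ]_λ = θ_λ / (10 · l · c · (n − 1))    [deg·cm²·dmol⁻¹]

with path length l in cm, peptide concentration c in mol/L and n residues
((n−1) peptide bonds); the factor 10 carries the mdeg and mol/L units into
deg·cm²·dmol⁻¹.  Peptide concentration is obtained from the absorbance of
the coupled fluorophore by Beer–Lambert, c = A/(ε·l); for TMR the
extinction coefficient at 556 nm is 90000 /M/cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CDSpectrum", "to_mre", "subtract_blank", "conc_from_absorbance",
           "TMR_EPSILON", "TMR_WAVELENGTH_NM"]

TMR_EPSILON = 90000.0  # /M/cm at 556 nm
TMR_WAVELENGTH_NM = 556.0


@dataclass
class CDSpectrum:
    """Observed ellipticity spectrum with the sample parameters needed for MRE."""

    wavelength: np.ndarray  # nm, strictly monotone (either direction)
    theta: np.ndarray       # observed ellipticity, millidegrees
    pathlength: float       # cm
    concentration: float    # mol/L
    n_residues: int

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.wavelength.shape != self.theta.shape:
            raise ValueError("wavelength and theta must match in length")
        d = np.diff(self.wavelength)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength must be strictly monotone")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.n_residues < 2:
            raise ValueError("need n_residues >= 2 (at least one peptide bond)")


def to_mre(spec: CDSpectrum) -> np.ndarray:
    """Mean residue ellipticity (deg·cm²·dmol⁻¹) at each wavelength."""
    denom = 10.0 * spec.pathlength * spec.concentration * (spec.n_residues - 1)
    return spec.theta / denom


def subtract_blank(spec: CDSpectrum, blank_theta) -> CDSpectrum:
    """Baseline correction: element-wise subtraction of a blank spectrum."""
    blank = np.asarray(blank_theta, dtype=float)
    if blank.shape != spec.theta.shape:
        raise ValueError("blank must match the spectrum in length")
    return CDSpectrum(spec.wavelength.copy(), spec.theta - blank,
                      spec.pathlength, spec.concentration, spec.n_residues)


def conc_from_absorbance(A: float, epsilon: float = TMR_EPSILON,
                         pathlength: float = 1.0) -> float:
    """Beer–Lambert concentration (mol/L) from dye absorbance."""
    if A < 0:
        raise ValueError("absorbance must be >= 0")
    if epsilon <= 0 or pathlength <= 0:
        raise ValueError("epsilon and pathlength must be positive")
    return A / (epsilon * pathlength)
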