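"""CD denaturation titration analysis.

Concentration from A210 via Beer–Lambert, mean-residue ellipticity, and the
two-state fraction folded

    F(C) = (θ(C) - θ_D) / (θ_N - θ_D)

with θ_N the native (C = 0) and θ_D the denatured-endpoint ellipticity.
Thermodynamic m-value/ΔG fitting is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPSILON_210",
    "TitrationSeries",
    "FoldedFractionCurve",
    "concentration_from_a210",
    "mean_residue_ellipticity",
    "fraction_folded",
]

# calculated 210 nm molar extinction coefficients (M^-1 cm^-1)
EPSILON_210 = {"W1": 270858.0, "W2": 543596.0}

DENATURANTS = {"urea", "GdmCl", "DPC", "NaCl"}


@dataclass(frozen=True)
class TitrationSeries:
    """Ellipticity (mdeg) versus denaturant concentration.

    ``axis_kind`` distinguishes molar concentrations (chaotropes) from
    protein:detergent molar ratios (DPC titrations).
    """

    denaturant: str
    concentrations: np.ndarray  # M or molar ratio, strictly increasing
    theta: np.ndarray  # mdeg
    axis_kind: str = "concentration_M"

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        t = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "theta", t)
        if self.denaturant not in DENATURANTS:
            raise ValueError(f"unknown denaturant {self.denaturant!r}")
        if c.shape != t.shape or c.ndim != 1 or c.size < 2:
            raise ValueError("need matching 1-D series with >= 2 points")
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be non-negative, increasing")


@dataclass(frozen=True)
class FoldedFractionCurve:
    concentrations: np.ndarray
    fraction: np.ndarray  # in [0, 1] after clamping
    theta_native: float
    theta_denatured: float
    clamped: np.ndarray  # bool flags where raw F fell outside [0, 1]

    @property
    def any_clamped(self) -> bool:
        return bool(self.clamped.any())


def concentration_from_a210(
    a210: float, epsilon: float, path_cm: float = 0.1
) -> float:
    """Protein concentration (M) from 210 nm absorbance: c = A/(ε·l)."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    if a210 < 0:
        raise ValueError("absorbance must be non-negative")
    return a210 / (epsilon * path_cm)


def mean_residue_ellipticity(
    theta_mdeg: float, concentration_m: float, path_cm: float, n_residues: int
) -> float:
    """Mean-residue ellipticity [θ] = θ/(10·c·l·n) in deg·cm²·dmol⁻¹.

    The denominator uses the residue count n (not n-1 peptide bonds); pass
    ``n_residues - 1`` for the bond convention.
    """
    if concentration_m <= 0 or path_cm <= 0 or n_residues <= 0:
        raise ValueError("concentration, path and residue count must be positive")
    return theta_mdeg / (10.0 * concentration_m * path_cm * n_residues)


def fraction_folded(
    series: TitrationSeries,
    theta_native: float | None = None,
    theta_denatured: float | None = None,
) -> FoldedFractionCurve:
    """Two-state fraction folded along a titration.

    θ_N defaults to the first (C = 0) point and θ_D to the highest
    concentration point.  Values outside [0, 1] are clamped and flagged
    rather than silently truncated.
    """
    theta_n = float(series.theta[0]) if theta_native is None else float(theta_native)
    theta_d = (
        float(series.theta[-1]) if theta_denatured is None else float(theta_denatured)
    )
    if theta_n == theta_d:
        raise ValueError("native and denatured ellipticities are identical")
    raw = (series.theta - theta_d) / (theta_n - theta_d)
    clamped = (raw < 0) | (raw > 1)
    return FoldedFractionCurve(
        concentrations=series.concentrations.copy(),
        fraction=np.clip(raw, 0.0, 1.0),
        theta_native=theta_n,
        theta_denatured=theta_d,
        clamped=clamped,
    )
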