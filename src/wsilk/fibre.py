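"""Fibre analytics: polarized Raman spectroscopy and tensile mechanics.

Raman processing follows the standard fibre workflow: cubic baseline
correction, 5-point smoothing, construction of an orientation-insensitive
spectrum from the four polarized geometries (ZZ, XX and the averaged
XZ/ZX cross terms; Z is the fibre long axis), and amide I band
(1600–1700 cm⁻¹) decomposition into α-helix, β-sheet and disordered
components whose relative areas give secondary-structure percentages.
The default orientation-insensitive weights and band table are documented,
configurable conventions — different instruments/references use different
coefficients, and results should quote the ones applied.

Tensile metrics are extracted from stress–strain curves truncated at
failure: breaking strength (max stress, MPa), breaking strain, toughness
(trapezoidal ∫σ dε; MPa·strain ≡ J·cm⁻³) and Young's modulus (least-squares
slope over an initial strain window, GPa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .io import XYTable

__all__ = [
    "ISO_WEIGHTS",
    "DEFAULT_BANDS",
    "PolarizedSpectra",
    "Band",
    "StressStrainCurve",
    "baseline_correct",
    "smooth5",
    "iso_spectrum",
    "decompose_amide_I",
    "orientation_ratio",
    "fibre_area",
    "tensile_metrics",
]

# weights over the symmetry-distinct polarized components; configurable
ISO_WEIGHTS = {"ZZ": 0.2, "XX": 0.4, "XZ": 0.4}

AMIDE_I_WINDOW = (1600.0, 1700.0)  # cm^-1


@dataclass(frozen=True)
class Band:
    label: str  # alpha_helix | beta_sheet | disorder
    center: float  # cm^-1
    width: float = 12.0  # initial Gaussian sigma, cm^-1
    shape: str = "gaussian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("band shape must be gaussian or lorentzian")


# Amide I component centers for protein fibres; the exact table is data,
# not code — override per experiment.
DEFAULT_BANDS = (
    Band("disorder", 1640.0),
    Band("alpha_helix", 1655.0),
    Band("beta_sheet", 1670.0),
    Band("disorder", 1685.0),
)


@dataclass(frozen=True)
class PolarizedSpectra:
    """The four polarized Raman spectra on a common wavenumber grid."""

    xx: XYTable
    xz: XYTable
    zx: XYTable
    zz: XYTable

    def __post_init__(self):
        grids = [self.xx.x, self.xz.x, self.zx.x, self.zz.x]
        for g in grids[1:]:
            if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
                raise ValueError("polarized spectra must share a wavenumber grid")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.xx.x

    @property
    def cross_mean(self) -> np.ndarray:
        """XZ and ZX averaged; they are equivalent under fibre symmetry."""
        return 0.5 * (self.xz.y + self.zx.y)


@dataclass(frozen=True)
class StressStrainCurve:
    """Stress (MPa) vs strain, truncated at the failure point."""

    strain: np.ndarray
    stress: np.ndarray  # MPa
    diameter_um: float = 1.5
    gauge_length_mm: float = 10.0

    def __post_init__(self):
        e = np.asarray(self.strain, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", e)
        object.__setattr__(self, "stress", s)
        if e.shape != s.shape or e.ndim != 1 or e.size < 2:
            raise ValueError("need matching 1-D strain/stress with >= 2 points")
        if np.any(e < 0) or np.any(np.diff(e) <= 0):
            raise ValueError("strain must be non-negative and increasing")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")


# ---------------------------------------------------------------------------
# Spectral preprocessing
# ---------------------------------------------------------------------------


def baseline_correct(spectrum: XYTable, anchor_regions) -> XYTable:
    """Subtract a cubic baseline fit to points inside ``anchor_regions``.

    ``anchor_regions`` is an iterable of (lo, hi) wavenumber windows taken
    to contain no bands; at least 4 anchor points are required to determine
    the cubic.
    """
    mask = np.zeros(len(spectrum), dtype=bool)
    for lo, hi in anchor_regions:
        mask |= (spectrum.x >= lo) & (spectrum.x <= hi)
    if mask.sum() < 4:
        raise ValueError("need at least 4 anchor points for a cubic baseline")
    coeffs = np.polynomial.polynomial.polyfit(spectrum.x[mask], spectrum.y[mask], 3)
    baseline = np.polynomial.polynomial.polyval(spectrum.x, coeffs)
    return spectrum.with_y(spectrum.y - baseline)


def smooth5(spectrum: XYTable) -> XYTable:
    """Centered 5-point moving average; the window shrinks at the ends."""
    if len(spectrum) < 5:
        raise ValueError("need at least 5 points for 5-point smoothing")
    y = spectrum.y
    out = np.empty_like(y)
    n = len(y)
    for i in range(n):
        half = min(2, i, n - 1 - i)
        out[i] = y[i - half : i + half + 1].mean()
    return spectrum.with_y(out)


def iso_spectrum(
    pol: PolarizedSpectra, weights: dict[str, float] | None = None
) -> XYTable:
    """Orientation-insensitive spectrum as a weighted combination.

    ``weights`` maps the symmetry-distinct components ZZ, XX and XZ (the
    XZ/ZX average) to coefficients summing to 1.
    """
    weights = dict(ISO_WEIGHTS if weights is None else weights)
    total = sum(weights.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9):
        raise ValueError("orientation-insensitive weights must sum to 1")
    y = (
        weights["ZZ"] * pol.zz.y
        + weights["XX"] * pol.xx.y
        + weights["XZ"] * pol.cross_mean
    )
    return XYTable(pol.wavenumbers.copy(), y, "wavenumber_cm-1")


# ---------------------------------------------------------------------------
# Amide I decomposition
# ---------------------------------------------------------------------------


def _component(shape: str, x, amplitude, center, width):
    if shape == "gaussian":
        return amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)
    return amplitude / (1.0 + ((x - center) / width) ** 2)


def _component_area(shape: str, amplitude, width):
    if shape == "gaussian":
        return amplitude * width * math.sqrt(2.0 * math.pi)
    return amplitude * width * math.pi


def decompose_amide_I(
    spectrum: XYTable,
    bands=DEFAULT_BANDS,
    window: tuple[float, float] = AMIDE_I_WINDOW,
    center_bound: float = 5.0,
    vary_centers: bool = True,
    vary_widths: bool = True,
) -> dict[str, float]:
    """Decompose the amide I band into component fractions (percent).

    Nonlinear least squares over ``window`` with each component's center
    bounded within ±``center_bound`` cm⁻¹ of the band table.  Fractions are
    component areas over the total fitted area, grouped by band label, and
    sum to 100.

    Heavily overlapped band tables (components < ~2 widths apart) make the
    area split degenerate when centers/widths float: the optimiser can
    trade area between neighbouring components at essentially zero cost in
    residual.  When the band table is trusted, set ``vary_centers`` and
    ``vary_widths`` to False to fit amplitudes only, which is well posed.
    """
    lo, hi = window
    sel = (spectrum.x >= lo) & (spectrum.x <= hi)
    if sel.sum() < 3 * len(bands):
        raise ValueError("amide I window not sufficiently covered by data")
    x = spectrum.x[sel]
    y = spectrum.y[sel]
    ymax = float(np.abs(y).max())
    if ymax == 0:
        raise ValueError("amide I window is empty (zero intensity)")

    params = lmfit.Parameters()
    for k, band in enumerate(bands):
        params.add(f"amp{k}", value=ymax / len(bands), min=0.0)
        params.add(
            f"cen{k}",
            value=band.center,
            min=band.center - center_bound,
            max=band.center + center_bound,
            vary=vary_centers,
        )
        params.add(f"wid{k}", value=band.width, min=2.0, max=40.0, vary=vary_widths)

    def residual(p):
        model = np.zeros_like(x)
        for k, band in enumerate(bands):
            model += _component(
                band.shape, x, p[f"amp{k}"].value, p[f"cen{k}"].value, p[f"wid{k}"].value
            )
        return model - y

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError(
            f"amide I fit did not converge: {result.message}; "
            f"residual norm {float(np.linalg.norm(result.residual)):.3g}"
        )
    areas: dict[str, float] = {}
    for k, band in enumerate(bands):
        area = _component_area(
            band.shape, result.params[f"amp{k}"].value, result.params[f"wid{k}"].value
        )
        areas[band.label] = areas.get(band.label, 0.0) + area
    total = sum(areas.values())
    if total <= 0:
        raise RuntimeError("amide I fit collapsed to zero area")
    fractions = {label: 100.0 * a / total for label, a in areas.items()}
    for label in ("alpha_helix", "beta_sheet", "disorder"):
        fractions.setdefault(label, 0.0)
    return fractions


def orientation_ratio(
    pol: PolarizedSpectra,
    band_position: float,
    half_window: float = 5.0,
    threshold: float = 0.15,
    aligned_when: str = "greater",
) -> dict:
    """Peak-height ratio R = I_XX/I_ZZ at a band with a qualitative call.

    ``aligned_when`` states the direction in which deviation from 1 is
    interpreted as alignment of the band's structural units along the
    fibre axis ('greater': R > 1 + threshold; 'less': R < 1 - threshold);
    the direction depends on the Raman tensor of the band in question.
    """
    sel = (pol.wavenumbers >= band_position - half_window) & (
        pol.wavenumbers <= band_position + half_window
    )
    if not sel.any():
        raise ValueError("band position outside the spectra")
    i_xx = float(pol.xx.y[sel].max())
    i_zz = float(pol.zz.y[sel].max())
    if i_zz <= 0:
        raise ValueError("zero ZZ intensity at the band position")
    ratio = i_xx / i_zz
    if aligned_when == "greater":
        aligned = ratio > 1.0 + threshold
    elif aligned_when == "less":
        aligned = ratio < 1.0 - threshold
    else:
        raise ValueError("aligned_when must be 'greater' or 'less'")
    call = "aligned along fibre axis" if aligned else "isotropic"
    return {"R": ratio, "call": call}


# ---------------------------------------------------------------------------
# Tensile mechanics
# ---------------------------------------------------------------------------


def fibre_area(diameter_estimates_um) -> dict:
    """Mean diameter (μm) and circular cross-section area (m²).

    Intended for the nine-estimate protocol: three positions per fibre,
    three measurements per micrograph, averaged before computing the area.
    """
    d = np.asarray(list(diameter_estimates_um), dtype=float)
    if d.size < 1:
        raise ValueError("need at least one diameter estimate")
    if np.any(d <= 0):
        raise ValueError("diameter estimates must be positive")
    mean_um = float(d.mean())
    radius_m = mean_um * 1e-6 / 2.0
    return {"mean_diameter_um": mean_um, "area_m2": math.pi * radius_m**2}


def tensile_metrics(
    curve: StressStrainCurve, modulus_window: tuple[float, float] = (0.0, 0.02)
) -> dict:
    """Breaking strength/strain, toughness and Young's modulus of a fibre.

    The curve is assumed truncated at failure, so the breaking point is the
    last recorded point.  Toughness is the trapezoidal integral of stress
    over strain (J·cm⁻³); the modulus is the least-squares slope over
    ``modulus_window`` (GPa).
    """
    strain = curve.strain
    stress = curve.stress
    toughness = float(np.trapezoid(stress, strain))
    lo, hi = modulus_window
    sel = (strain >= lo) & (strain <= hi)
    if sel.sum() < 2:
        sel = np.zeros_like(strain, dtype=bool)
        sel[:2] = True  # fall back to the first two points
    slope = np.polyfit(strain[sel], stress[sel], 1)[0]
    return {
        "breaking_strength_MPa": float(stress.max()),
        "breaking_strain": float(strain[-1]),
        "toughness_J_per_cm3": toughness,
        "youngs_modulus_GPa": float(slope) / 1e3,
    }
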