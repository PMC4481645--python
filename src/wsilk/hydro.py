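"""Coordinate-ensemble hydrodynamics: radius of gyration and a Kirkwood
bead-model translational diffusion coefficient.

The Kirkwood approximation treats the molecule as N beads and neglects
rotational coupling and volume corrections:

    Dt = kB*T/(6*pi*eta) * (1/N^2) * [sum_i 1/sigma_i + sum_{i!=j} 1/R_ij]

It is used here for trend-level comparison of structural ensembles against
DOSY-measured diffusion; no agreement with shell-model codes (HYDROPRO) is
claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .dosy import KB, HydroResult
from .io import Ensemble, Model, get_logger

__all__ = [
    "BeadModel",
    "EnsembleHydroReport",
    "rg_from_coordinates",
    "beads_from_model",
    "kirkwood_dc",
    "ensemble_hydro_report",
]

DEFAULT_BEAD_RADIUS_A = 3.8  # hydration-inflated per-residue bead, Å

_log = get_logger(__name__)

# united-atom masses for optional mass weighting
_ATOM_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass(frozen=True)
class BeadModel:
    """Spherical-bead representation of one conformer."""

    centers: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) Å
    temperature: float = 303.15  # K
    eta_cP: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "radii", r)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
            raise ValueError("centers must be (n>=1, 3)")
        if r.shape != (c.shape[0],) or np.any(r <= 0):
            raise ValueError("radii must be positive, one per bead")


@dataclass(frozen=True)
class EnsembleHydroReport:
    """Per-model Rg/Dc with ensemble statistics and DOSY comparison."""

    rg_per_model: np.ndarray  # Å
    dc_per_model: np.ndarray  # cm^2/s
    rg_mean: float
    rg_sd: float
    dc_mean: float
    dc_sd: float
    dosy_dc: float | None = None
    relative_deviation: float | None = None  # (ensemble mean - DOSY)/DOSY

    def as_dict(self) -> dict:
        return {
            "Rg_per_model_A": list(map(float, self.rg_per_model)),
            "Dc_per_model_cm2_per_s": list(map(float, self.dc_per_model)),
            "Rg_mean_A": self.rg_mean,
            "Rg_sd_A": self.rg_sd,
            "Dc_mean_cm2_per_s": self.dc_mean,
            "Dc_sd_cm2_per_s": self.dc_sd,
            "DOSY_Dc_cm2_per_s": self.dosy_dc,
            "relative_deviation": self.relative_deviation,
        }


def rg_from_coordinates(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Radius of gyration (Å): sqrt(sum w |r - rbar|^2 / sum w).

    Unweighted by default; pass per-atom ``masses`` for mass weighting.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    w = np.ones(coords.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    centre = np.average(coords, axis=0, weights=w)
    sq = np.sum((coords - centre) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def model_rg(model: Model, mass_weighted: bool = False) -> float:
    masses = None
    if mass_weighted:
        masses = np.array([_ATOM_MASS.get(e, 12.011) for e in model.element])
    return rg_from_coordinates(model.coords, masses)


def beads_from_model(
    model: Model,
    bead_rule: str = "calpha",
    bead_radius: float = DEFAULT_BEAD_RADIUS_A,
    temperature: float = 303.15,
    eta_cP: float = 1.0,
) -> BeadModel:
    """Build a bead model from a conformer.

    ``calpha`` (default): one bead per residue at the CA position with a
    uniform effective radius.  Residues lacking a CA are skipped with a
    warning.  ``heavy``: one bead per non-hydrogen atom.
    """
    if bead_rule == "calpha":
        centers = []
        for res in np.unique(model.residue_number):
            ca = model.atom_coord(int(res), "CA")
            if ca is None:
                _log.warning("residue %d has no CA; bead skipped", res)
                continue
            centers.append(ca)
        centers = np.asarray(centers, dtype=float)
    elif bead_rule == "heavy":
        mask = model.element != "H"
        centers = model.coords[mask]
    else:
        raise ValueError(f"unknown bead rule {bead_rule!r}")
    if centers.shape[0] == 0:
        raise ValueError("bead model is empty")
    radii = np.full(centers.shape[0], float(bead_radius))
    return BeadModel(centers, radii, temperature=temperature, eta_cP=eta_cP)


def kirkwood_dc(beads: BeadModel) -> float:
    """Kirkwood double-sum translational diffusion coefficient (cm^2/s)."""
    n = beads.centers.shape[0]
    diag = float(np.sum(1.0 / beads.radii))
    pair = 0.0
    if n > 1:
        dists = pdist(beads.centers)
        if np.any(dists < 1e-6):
            raise ValueError("coincident bead centers")
        # overlapping beads are tolerated: the pair term uses the center
        # distance regardless, which slightly overestimates friction
        pair = float(2.0 * np.sum(1.0 / dists))  # i != j, both orders
    eta_si = beads.eta_cP * 1e-3
    prefactor = KB * beads.temperature / (6.0 * math.pi * eta_si)
    dt_si_per_a = prefactor * (diag + pair) / n**2  # per Å^-1 -> needs Å->m
    dt_si = dt_si_per_a / 1e-10
    return dt_si * 1e4  # m^2/s -> cm^2/s


def ensemble_hydro_report(
    ensemble: Ensemble,
    dosy: HydroResult | float | None = None,
    bead_rule: str = "calpha",
    bead_radius: float = DEFAULT_BEAD_RADIUS_A,
    temperature: float = 303.15,
    eta_cP: float = 1.0,
) -> EnsembleHydroReport:
    """Per-model Rg and Kirkwood Dc with mean ± s.d. and DOSY comparison."""
    rgs, dcs = [], []
    for model in ensemble.models():
        rgs.append(rg_from_coordinates(model.coords))
        beads = beads_from_model(
            model,
            bead_rule=bead_rule,
            bead_radius=bead_radius,
            temperature=temperature,
            eta_cP=eta_cP,
        )
        dcs.append(kirkwood_dc(beads))
    rgs = np.asarray(rgs)
    dcs = np.asarray(dcs)
    dosy_dc = dosy.Dc if isinstance(dosy, HydroResult) else dosy
    rel = None
    if dosy_dc is not None:
        rel = float((dcs.mean() - dosy_dc) / dosy_dc)
    return EnsembleHydroReport(
        rg_per_model=rgs,
        dc_per_model=dcs,
        rg_mean=float(rgs.mean()),
        rg_sd=float(rgs.std(ddof=0)),
        dc_mean=float(dcs.mean()),
        dc_sd=float(dcs.std(ddof=0)),
        dosy_dc=dosy_dc,
        relative_deviation=rel,
    )
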