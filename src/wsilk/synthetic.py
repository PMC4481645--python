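"""Seeded synthetic-data generators emulating every input class.

Each generator is a deterministic function of its seed and parameters.
Defaults encode the study conditions of the aciniform W-unit system: a
199-residue repeat with ~50% Gly/Ala/Ser, phenylalanines at 90 and 95 and
a proline-rich linker stretch; a globular helical core over residues
12–149 flanked by disordered tails; 16-step 2–95% gradient DOSY decays;
junction-localised shift perturbations between concatemer units; two-state
denaturation curves; band-plus-baseline polarized Raman spectra; and
linear-plus-plastic stress–strain curves.

Coordinate generation builds ideal-geometry backbones from φ/ψ tables
(helices at φ=-57°, ψ=-47°) with disordered segments sampled as a simple
self-avoiding walk — sufficient for hydrodynamic/r.m.s.d. contrast, not a
physical ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .denaturation import TitrationSeries
from .dosy import DecayCurve, PFGParams, gradient_from_percent, stejskal_tanner
from .fibre import (
    DEFAULT_BANDS,
    ISO_WEIGHTS,
    PolarizedSpectra,
    StressStrainCurve,
    _component,
)
from .io import Ensemble, ShiftTable, XYTable
from .restraints import DihedralRestraint, DistanceRestraint, RestraintSet

__all__ = [
    "GeneratorConfig",
    "DEFAULT_HELIX_TABLE",
    "CORE_RANGE",
    "gen_w_sequence",
    "gen_beads_on_string_ensemble",
    "gen_dosy_decay",
    "gen_shift_tables",
    "gen_hetnoe_profile",
    "gen_titration",
    "gen_raman",
    "gen_stress_strain",
    "gen_restraints_from_ensemble",
]

W_UNIT_LENGTH = 199
CORE_RANGE = (12, 149)
PROLINE_STRETCH = (172, 191)

# Helix boundaries: only helix 5 (135-149) is experimentally pinned; the
# others are illustrative defaults placing 5 helical segments inside the
# 12-149 core with short turns, leaving 40-60 as structured non-helical.
DEFAULT_HELIX_TABLE = ((12, 39), (61, 86), (89, 110), (113, 132), (135, 149))


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed plus per-generator keyword parameters (bit-reproducible)."""

    seed: int = 0
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequence
# ---------------------------------------------------------------------------

_GAS = ("G", "A", "S")
_FILLER = ("T", "N", "Q", "L", "V", "I", "D", "E", "R", "K")
_AROMATIC = ("Y", "F")


def gen_w_sequence(
    seed: int = 0,
    length: int = W_UNIT_LENGTH,
    gas_fraction: float = 0.50,
    n_prolines: int = 8,
    n_linker_prolines: int = 6,
    proline_stretch: tuple[int, int] = PROLINE_STRETCH,
    phe_positions: tuple[int, int] = (90, 95),
    n_other_aromatics: int = 8,
) -> str:
    """A W-unit-like amino acid sequence satisfying composition constraints.

    Defaults: 199 residues, Gly+Ala+Ser fraction ~0.50, Phe at 90 and 95,
    8 aromatic residues besides the two Phe, and exactly 8 prolines of
    which 6 fall in the 172-191 linker stretch.
    """
    rng = np.random.default_rng(seed)
    if length < proline_stretch[1]:
        raise ValueError("length too short for the proline stretch")
    n_gas = int(round(gas_fraction * length))
    stretch = list(range(proline_stretch[0], proline_stretch[1] + 1))
    if n_linker_prolines > len(stretch) or n_linker_prolines > n_prolines:
        raise ValueError("infeasible proline placement")

    seq = np.empty(length + 1, dtype="<U1")  # 1-based
    seq[:] = ""
    for pos in phe_positions:
        seq[pos] = "F"
    linker_pro = rng.choice(stretch, size=n_linker_prolines, replace=False)
    for pos in linker_pro:
        seq[pos] = "P"
    outside = [
        p
        for p in range(1, length + 1)
        if seq[p] == "" and not (proline_stretch[0] <= p <= proline_stretch[1])
    ]
    other_pro = rng.choice(outside, size=n_prolines - n_linker_prolines, replace=False)
    for pos in other_pro:
        seq[pos] = "P"
    free = [p for p in range(1, length + 1) if seq[p] == ""]
    aromatic_pos = rng.choice(free, size=n_other_aromatics, replace=False)
    for pos in aromatic_pos:
        seq[pos] = rng.choice(_AROMATIC)
    free = [p for p in range(1, length + 1) if seq[p] == ""]
    if n_gas > len(free):
        raise ValueError("infeasible Gly/Ala/Ser fraction")
    gas_pos = rng.choice(free, size=n_gas, replace=False)
    for pos in gas_pos:
        seq[pos] = rng.choice(_GAS)
    for pos in range(1, length + 1):
        if seq[pos] == "":
            seq[pos] = rng.choice(_FILLER)
    out = "".join(seq[1:])
    gas_actual = sum(out.count(a) for a in _GAS) / length
    if not 0.45 <= gas_actual <= 0.55:
        raise ValueError("generated sequence violates the Gly/Ala/Ser window")
    return out


# ---------------------------------------------------------------------------
# Backbone builder (ideal geometry, NeRF chain extension)
# ---------------------------------------------------------------------------

_B_NCA, _B_CAC, _B_CN, _B_CO = 1.458, 1.525, 1.329, 1.231
_A_CNCA, _A_NCAC, _A_CACN, _A_CACO = 121.7, 111.2, 116.2, 120.8
ALPHA_PHI, ALPHA_PSI = -57.0, -47.0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone N, CA, C, O coordinates (n_res, 4, 3) from φ/ψ (degrees).

    φ of the first residue and ψ of the last are ignored (undefined); the
    peptide bond is kept trans (ω = 180°).
    """
    n_res = len(phi)
    coords = np.zeros((n_res, 4, 3))
    coords[0, 0] = [0.0, 0.0, 0.0]  # N
    coords[0, 1] = [_B_NCA, 0.0, 0.0]  # CA
    ang = math.radians(_A_NCAC)
    coords[0, 2] = coords[0, 1] + _B_CAC * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(n_res - 1):
        n_i, ca_i, c_i = coords[i, 0], coords[i, 1], coords[i, 2]
        n_next = _place_atom(n_i, ca_i, c_i, _B_CN, _A_CACN, psi[i])
        ca_next = _place_atom(ca_i, c_i, n_next, _B_NCA, _A_CNCA, 180.0)
        c_next = _place_atom(c_i, n_next, ca_next, _B_CAC, _A_NCAC, phi[i + 1])
        coords[i + 1, 0] = n_next
        coords[i + 1, 1] = ca_next
        coords[i + 1, 2] = c_next
        coords[i, 3] = _place_atom(n_i, ca_i, c_i, _B_CO, _A_CACO, psi[i] + 180.0)
    # terminal carbonyl O: use the stored (unused) terminal psi
    last = n_res - 1
    coords[last, 3] = _place_atom(
        coords[last, 0], coords[last, 1], coords[last, 2], _B_CO, _A_CACO,
        psi[last] + 180.0,
    )
    return coords


# coil φ/ψ basins (φ, ψ, half-spread): β, ppII and left-handed turn.
# The right-handed α basin is deliberately excluded so disordered segments
# never emit persistent helical stretches.
_COIL_BASINS = ((-120.0, 130.0, 25.0), (-75.0, 150.0, 20.0), (60.0, 30.0, 20.0))


def _sample_coil(rng, prev_basin: int = -1) -> tuple[float, float, int]:
    # never draw the turn basin twice in a row: disordered segments must
    # not accumulate persistent helical H-bond ladders
    choices = len(_COIL_BASINS) - (1 if prev_basin == len(_COIL_BASINS) - 1 else 0)
    basin = int(rng.integers(choices))
    phi0, psi0, spread = _COIL_BASINS[basin]
    return (
        float(phi0 + rng.uniform(-spread, spread)),
        float(psi0 + rng.uniform(-spread, spread)),
        basin,
    )


def _chain_with_avoidance(
    phi_fixed: np.ndarray,
    psi_fixed: np.ndarray,
    free_mask: np.ndarray,
    rng,
    min_ca_dist: float = 3.8,
    max_tries: int = 40,
) -> np.ndarray:
    """Build a backbone, resampling free residues' φ/ψ to avoid CA clashes."""
    n_res = len(phi_fixed)
    phi = phi_fixed.copy()
    psi = psi_fixed.copy()
    for attempt in range(max_tries):
        basin = -1
        for i in np.flatnonzero(free_mask):
            phi[i], psi[i], basin = _sample_coil(rng, basin)
        coords = _build_backbone(phi, psi)
        ca = coords[:, 1]
        ok = True
        for i in range(n_res):
            d = np.linalg.norm(ca[: max(0, i - 2)] - ca[i], axis=1)
            if d.size and d.min() < min_ca_dist:
                ok = False
                break
        if ok:
            break
    return coords, phi, psi  # last attempt accepted if never clash-free


def gen_beads_on_string_ensemble(
    seed: int = 0,
    n_units: int = 1,
    n_models: int = 10,
    helix_table=DEFAULT_HELIX_TABLE,
    unit_length: int = W_UNIT_LENGTH,
    core_range: tuple[int, int] = CORE_RANGE,
    extended: bool = False,
) -> Ensemble:
    """Backbone-only coordinate ensemble of a beads-on-a-string concatemer.

    Helical segments use ideal α geometry; non-helical core residues
    (turns and the 40-60 stretch) receive coil dihedrals drawn once per
    ensemble so the core superposes across models, while tail/linker
    residues outside the core are resampled per model.  ``extended=True``
    builds fully extended chains (φ = ψ = 180°) of identical composition,
    for compact-vs-extended comparisons.
    """
    segs = sorted(helix_table)
    for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
        if a2 <= b1:
            raise ValueError("overlapping helix segments")
    n_res = n_units * unit_length
    rng = np.random.default_rng(seed)

    helix_mask = np.zeros(n_res + 1, dtype=bool)  # 1-based
    core_mask = np.zeros(n_res + 1, dtype=bool)
    for unit in range(n_units):
        off = unit * unit_length
        for a, b in segs:
            helix_mask[a + off : b + off + 1] = True
        core_mask[core_range[0] + off : core_range[1] + off + 1] = True

    phi = np.zeros(n_res)
    psi = np.zeros(n_res)
    free_core = np.zeros(n_res, dtype=bool)
    free_tail = np.zeros(n_res, dtype=bool)
    for res in range(1, n_res + 1):
        idx = res - 1
        if helix_mask[res]:
            phi[idx], psi[idx] = ALPHA_PHI, ALPHA_PSI
        elif core_mask[res]:
            free_core[idx] = True
        else:
            free_tail[idx] = True

    if extended:
        phi[:] = 180.0
        psi[:] = 180.0
        base_phi, base_psi = phi, psi
    else:
        # draw the structured-but-non-helical core dihedrals once so the
        # core superposes across models
        core_rng = np.random.default_rng(rng.integers(2**31))
        _, base_phi, base_psi = _chain_with_avoidance(phi, psi, free_core, core_rng)

    models = []
    for _ in range(n_models):
        if extended:
            coords = _build_backbone(base_phi, base_psi)
        else:
            coords, _, _ = _chain_with_avoidance(
                base_phi, base_psi, free_tail,
                np.random.default_rng(rng.integers(2**31)),
            )
        models.append(coords)
    stack = np.stack(models)  # (m, n_res, 4, 3)

    atom_names = np.tile(np.array(["N", "CA", "C", "O"]), n_res)
    residue_numbers = np.repeat(np.arange(1, n_res + 1), 4)
    residue_names = np.repeat(np.array(["GLY"] * n_res), 4)
    elements = np.tile(np.array(["N", "C", "C", "O"]), n_res)
    chain = np.full(4 * n_res, "A")
    coords = stack.reshape(n_models, 4 * n_res, 3)
    return Ensemble(
        coords=coords,
        atom_name=atom_names,
        residue_number=residue_numbers,
        residue_name=residue_names,
        chain_id=chain,
        element=elements,
    )


# ---------------------------------------------------------------------------
# DOSY decays
# ---------------------------------------------------------------------------


def gen_dosy_decay(
    seed: int = 0,
    Dc_true: float = 1.1e-6,
    I0: float = 1.0,
    noise_sigma: float = 0.01,
    n_steps: int = 16,
    pct_range: tuple[float, float] = (2.0, 95.0),
    params: PFGParams | None = None,
) -> DecayCurve:
    """Stejskal–Tanner decay over a 2–95% gradient ramp with Gaussian noise.

    ``noise_sigma`` is expressed as a fraction of I0.  ``Dc_true`` defaults
    to a ~19 kDa globular-protein diffusion coefficient in water at 303 K.
    """
    params = params or PFGParams()
    rng = np.random.default_rng(seed)
    pct = np.linspace(pct_range[0], pct_range[1], n_steps)
    g = gradient_from_percent(pct, params)
    intensity = stejskal_tanner(I0, Dc_true, g, params)
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_sigma * I0, size=n_steps)
        intensity = np.clip(intensity, 1e-6 * I0, None)
    return DecayCurve(g, intensity, params)


# ---------------------------------------------------------------------------
# Chemical shift tables
# ---------------------------------------------------------------------------

_SHIFT_CENTERS = {"H": (8.3, 0.45), "N": (119.0, 4.0), "CA": (58.0, 2.5), "CO": (176.0, 1.8)}


def gen_shift_tables(
    seed: int = 0,
    length: int = W_UNIT_LENGTH,
    repeat_length: int = 200,
    junction_width: int = 3,
    perturbation_ppm: float = 0.25,
    noise_ppm: float = 0.002,
) -> dict[str, ShiftTable]:
    """Shift tables for an isolated unit and both units of a 2-unit concatemer.

    The concatemer unit tables equal the isolated-unit table up to Gaussian
    noise everywhere except the ``junction_width`` residues adjacent to the
    covalent link, which receive an additional perturbation of amplitude
    ``perturbation_ppm`` (scaled per nucleus by the inverse CSD weight so
    the combined displacement is comparable across nuclei).
    """
    rng = np.random.default_rng(seed)
    residues = np.arange(1, length + 1)
    base = {}
    for nucleus, (centre, spread) in _SHIFT_CENTERS.items():
        base[nucleus] = centre + rng.normal(0.0, spread, size=length)

    def table(offset: int, junction: np.ndarray, condition: str) -> ShiftTable:
        rows = []
        for i, res in enumerate(residues):
            for nucleus in _SHIFT_CENTERS:
                shift = base[nucleus][i]
                if noise_ppm > 0 and offset >= 0:
                    shift = shift + rng.normal(0.0, noise_ppm)
                if res in junction:
                    scale = {"H": 1.0, "N": 1 / 0.102, "CA": 1 / 0.251, "CO": 1 / 0.251}
                    shift = shift + perturbation_ppm * scale[nucleus]
                rows.append(
                    {
                        "residue": int(res) + max(offset, 0),
                        "residue_name": "XAA",
                        "nucleus": nucleus,
                        "shift": float(shift),
                    }
                )
        return ShiftTable(pd.DataFrame(rows), condition=condition)

    none = np.array([], dtype=int)
    junction_1 = residues[-junction_width:]  # C-terminal side of the link
    junction_2 = residues[:junction_width]  # N-terminal side of the link
    return {
        "W1": table(-1, none, "W1"),
        "W2-1": table(0, junction_1, "W2-1"),
        "W2-2": table(repeat_length, junction_2, "W2-2"),
    }


# ---------------------------------------------------------------------------
# hetNOE profiles
# ---------------------------------------------------------------------------


def hetnoe_truth(
    length: int = W_UNIT_LENGTH,
    core_range: tuple[int, int] = CORE_RANGE,
    plateau: float = 0.80,
    tail_value: float = -0.2,
) -> np.ndarray:
    """Noise-free per-residue enhancement factors (index 0 = residue 1)."""
    first, last = core_range
    values = np.full(length, plateau)
    for res in range(1, first):
        values[res - 1] = max(tail_value, plateau - 0.2 * (first - res))
    edge = 0.55
    for res in range(last + 1, length + 1):
        frac = (res - (last + 1)) / max(1, length - last - 1)
        values[res - 1] = edge + (tail_value - edge) * frac
    return values


def gen_hetnoe_profile(
    seed: int = 0,
    length: int = W_UNIT_LENGTH,
    core_range: tuple[int, int] = CORE_RANGE,
    plateau: float = 0.80,
    tail_value: float = -0.2,
    noise_sigma: float = 0.02,
) -> dict[str, pd.DataFrame]:
    """Saturated/reference peak-height tables with an ordered-core profile.

    The rigid core (default residues 12–149) sits at the plateau; tails
    decline towards negative values, emulating ps–ns flexible termini.
    """
    rng = np.random.default_rng(seed)
    truth = hetnoe_truth(length, core_range, plateau, tail_value)
    residues = np.arange(1, length + 1)
    ref = rng.lognormal(mean=0.0, sigma=0.2, size=length)
    noe = truth + (rng.normal(0.0, noise_sigma, size=length) if noise_sigma > 0 else 0.0)
    sat = ref * noe
    return {
        "sat": pd.DataFrame({"residue": residues, "height": sat}),
        "ref": pd.DataFrame({"residue": residues, "height": ref}),
    }


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

R_KJ = 8.314462618e-3  # kJ/(mol*K)


def gen_titration(
    seed: int = 0,
    denaturant: str = "urea",
    c_max: float = 5.0,
    n_points: int = 11,
    Cm: float = 1.5,
    m_value: float = 8.0,  # kJ/mol/M
    temperature: float = 295.15,
    theta_native: float = -20000.0,
    theta_denatured: float = -2000.0,
    noise_mdeg: float = 0.0,
) -> TitrationSeries:
    """Two-state denaturation curve θ(C) with logistic folded fraction.

    F(C) = 1 / (1 + exp(m (C - Cm) / RT)); θ interpolates linearly between
    the native and denatured ellipticities.
    """
    rng = np.random.default_rng(seed)
    conc = np.linspace(0.0, c_max, n_points)
    f = 1.0 / (1.0 + np.exp(m_value * (conc - Cm) / (R_KJ * temperature)))
    theta = theta_denatured + f * (theta_native - theta_denatured)
    if noise_mdeg > 0:
        theta = theta + rng.normal(0.0, noise_mdeg, size=n_points)
    return TitrationSeries(denaturant, conc, theta)


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------


def gen_raman(
    seed: int = 0,
    fractions: dict[str, float] | None = None,
    orientation: float = 0.0,
    baseline_coeffs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    grid: tuple[float, float, float] = (1500.0, 1800.0, 1.0),
    bands=DEFAULT_BANDS,
    weights: dict[str, float] | None = None,
) -> PolarizedSpectra:
    """Four polarized spectra consistent with a known isotropic spectrum.

    The amide I region is synthesised from ``fractions`` (percent per
    label, default the fibre-like 32/28/40 α/β/disorder split); a uniaxial
    ``orientation`` in (-1, 1) scales ZZ by (1+o) and XX by (1-o), with the
    cross term chosen so the configured orientation-insensitive weights
    recover the isotropic spectrum exactly.  A cubic baseline (coefficients
    in ascending order, evaluated on a unit-scaled wavenumber axis) and
    Gaussian noise can be superimposed.
    """
    rng = np.random.default_rng(seed)
    fractions = dict(fractions or {"alpha_helix": 32.0, "beta_sheet": 28.0, "disorder": 40.0})
    weights = dict(ISO_WEIGHTS if weights is None else weights)
    if not -1.0 < orientation < 1.0:
        raise ValueError("orientation must lie in (-1, 1)")
    x = np.arange(grid[0], grid[1] + grid[2] / 2, grid[2])

    n_per_label: dict[str, int] = {}
    for band in bands:
        n_per_label[band.label] = n_per_label.get(band.label, 0) + 1
    iso = np.zeros_like(x)
    for band in bands:
        area = fractions.get(band.label, 0.0) / n_per_label[band.label]
        amplitude = area / (band.width * math.sqrt(2.0 * math.pi))
        iso += _component("gaussian", x, amplitude, band.center, band.width)

    f_zz = 1.0 + orientation
    f_xx = 1.0 - orientation
    f_xz = (1.0 - weights["ZZ"] * f_zz - weights["XX"] * f_xx) / weights["XZ"]
    if f_xz <= 0:
        raise ValueError("orientation incompatible with the configured weights")

    u = (x - x[0]) / (x[-1] - x[0])  # unit axis for baseline stability
    baseline = np.polynomial.polynomial.polyval(u, np.asarray(baseline_coeffs))

    def channel(factor: float) -> XYTable:
        y = factor * iso + baseline
        if noise_sigma > 0:
            y = y + rng.normal(0.0, noise_sigma, size=x.size)
        return XYTable(x.copy(), y, "wavenumber_cm-1")

    return PolarizedSpectra(
        xx=channel(f_xx), xz=channel(f_xz), zx=channel(f_xz), zz=channel(f_zz)
    )


# ---------------------------------------------------------------------------
# Stress-strain curves
# ---------------------------------------------------------------------------


def gen_stress_strain(
    seed: int = 0,
    E_GPa: float = 1.7,
    yield_strain: float = 0.02,
    break_strain: float = 0.30,
    hardening_MPa: float = 120.0,
    n_points: int = 200,
    noise_MPa: float = 0.0,
) -> StressStrainCurve:
    """Linear-elastic then linear-plastic stress–strain curve to failure."""
    rng = np.random.default_rng(seed)
    if break_strain <= 0:
        raise ValueError("break strain must be positive")
    strain = np.linspace(0.0, break_strain, n_points)[1:]
    strain = np.insert(strain, 0, 0.0)
    e_mpa = E_GPa * 1e3
    stress = np.where(
        strain <= yield_strain,
        e_mpa * strain,
        e_mpa * yield_strain + hardening_MPa * (strain - yield_strain),
    )
    if noise_MPa > 0:
        stress = stress + rng.normal(0.0, noise_MPa, size=strain.size)
        stress[0] = 0.0
    return StressStrainCurve(strain=strain, stress=stress)


# ---------------------------------------------------------------------------
# Restraints from an ensemble
# ---------------------------------------------------------------------------


def gen_restraints_from_ensemble(
    ensemble: Ensemble,
    cutoff: float = 5.0,
    slack: float = 0.5,
    dihedral_tolerance: float = 20.0,
) -> RestraintSet:
    """Distance/dihedral restraints trivially satisfied by their source.

    One CA–CA distance restraint (upper = largest observed distance plus
    ``slack``) is emitted per residue pair within ``cutoff`` in every
    model, mimicking NOE-style contact restraints; φ/ψ restraints are
    emitted for residues assigned helical in the first model, targeted at
    the circular mean over models.
    """
    from .metrics import assign_ss, dihedrals

    out = RestraintSet()
    if cutoff <= 0:
        return out
    ca_mask = ensemble.atom_name == "CA"
    residues = ensemble.residue_number[ca_mask]
    coords = ensemble.coords[:, ca_mask]  # (m, n_res, 3)
    n = len(residues)
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))  # (m, n, n)
    dmax = dist.max(axis=0)
    within = dist.max(axis=0) < cutoff
    for i in range(n):
        for j in range(i + 1, n):
            if within[i, j]:
                out.distances.append(
                    DistanceRestraint.simple(
                        int(residues[i]), "CA", int(residues[j]), "CA",
                        0.0, float(dmax[i, j] + slack),
                    )
                )
    ss = assign_ss(ensemble.model(0))
    helical = set(ss.index[ss == "H"])
    if helical:
        tables = [dihedrals(m).set_index("residue") for m in ensemble.models()]
        for res in sorted(helical):
            for angle in ("phi", "psi"):
                values = np.array([t.at[res, angle] for t in tables if res in t.index])
                values = values[~np.isnan(values)]
                if values.size == 0:
                    continue
                rad = np.radians(values)
                mean = math.degrees(
                    math.atan2(np.sin(rad).mean(), np.cos(rad).mean())
                )
                out.dihedrals.append(
                    DihedralRestraint(int(res), angle, mean, dihedral_tolerance)
                )
    return out
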