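"""Ensemble structural metrics: superposition/r.m.s.d., secondary-structure
assignment, backbone dihedrals and solvent exposure.

Secondary structure follows the Kabsch–Sander scheme: a backbone H-bond is
assigned when the electrostatic pairing energy

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol, r in Å]

between an amide donor (N-H) and a carbonyl acceptor (C=O) falls below
-0.5 kcal/mol.  Helices arise from runs of at least two consecutive
i -> i+k turns (k = 3, 4, 5; all helix classes are merged into 'H'),
strands/bridges ('E') from the parallel/antiparallel ladder patterns, and
everything else is coil ('C').  Amide protons absent from the model are
reconstructed 1.01 Å from N along the bisector opposite the preceding
carbonyl carbon and CA.  Solvent accessibility uses Shrake–Rupley sphere
sampling on heavy atoms with a 1.4 Å probe, reported relative to
extended-state Gly-X-Gly reference areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BACKBONE_ATOMS, Ensemble, Model, get_logger

__all__ = [
    "SuperpositionResult",
    "superpose",
    "ensemble_rmsd",
    "assign_ss",
    "ss_fractions",
    "dihedrals",
    "alpha_fraction",
    "ensemble_alpha_fraction",
    "sasa_ranking",
    "shrake_rupley_sasa",
]

_log = get_logger(__name__)

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
KS_COUPLING = 27.888  # kcal*Å/mol (q1*q2*f in the Kabsch–Sander energy)

DEFAULT_ALPHA_PHI = (-100.0, -30.0)  # deg
DEFAULT_ALPHA_PSI = (-80.0, -5.0)  # deg

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70

# Theoretical maximum accessible surface areas (Å^2) of residue X in an
# extended Gly-X-Gly tripeptide (Tien et al. 2013, theoretical set).
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å
    selection: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation/translation of ``mobile`` onto ``reference``."""
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    p = mobile - mu_m
    q = reference - mu_r
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = mu_r - rot @ mu_m
    moved = p @ rot.T + mu_r
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def _selection_mask(model: Model, atom_class: str, residue_range=None) -> np.ndarray:
    if atom_class == "backbone":
        mask = model.mask(atom_names=BACKBONE_ATOMS, residue_range=residue_range)
    elif atom_class == "heavy":
        mask = model.mask(residue_range=residue_range) & (model.element != "H")
    else:
        raise ValueError(f"unknown atom class {atom_class!r}")
    return mask


def superpose(
    mobile: Model,
    reference: Model,
    atom_class: str = "backbone",
    residue_range: tuple[int, int] | None = None,
) -> SuperpositionResult:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``."""
    mask = _selection_mask(mobile, atom_class, residue_range)
    pm = mobile.coords[mask]
    pr = reference.coords[mask]
    if pm.shape[0] < 3:
        raise ValueError("selection must contain at least 3 atom pairs")
    spread = np.linalg.svd(pm - pm.mean(axis=0), compute_uv=False)
    if spread[1] < 1e-8:
        raise ValueError("selection is collinear; superposition ill-defined")
    rot, trans, rmsd = _kabsch(pm, pr)
    desc = f"{atom_class}" + (f" {residue_range[0]}:{residue_range[1]}" if residue_range else "")
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, selection=desc)


def ensemble_rmsd(
    ensemble: Ensemble,
    atom_class: str = "backbone",
    residue_range: tuple[int, int] | None = None,
    mode: str = "pairwise",
) -> tuple[float, float]:
    """Mean ± s.d. r.m.s.d. over an ensemble after per-pair superposition.

    ``pairwise`` averages over all unordered model pairs; ``to_reference``
    superposes every model onto the first (by convention the lowest-energy
    structure of a deposited NMR ensemble).
    """
    if ensemble.n_models < 2:
        raise ValueError("ensemble r.m.s.d. needs at least 2 models")
    mask = _selection_mask(ensemble.model(0), atom_class, residue_range)
    if not mask.any():
        raise ValueError("empty selection")
    coords = ensemble.coords[:, mask]
    if mode == "pairwise":
        pairs = [
            (i, j)
            for i in range(ensemble.n_models)
            for j in range(i + 1, ensemble.n_models)
        ]
    elif mode == "to_reference":
        pairs = [(0, j) for j in range(1, ensemble.n_models)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    values = np.array([_kabsch(coords[j], coords[i])[2] for i, j in pairs])
    return float(values.mean()), float(values.std(ddof=0))


# ---------------------------------------------------------------------------
# Kabsch–Sander secondary structure
# ---------------------------------------------------------------------------


def _backbone_by_residue(model: Model) -> pd.DataFrame:
    """Backbone atom coordinates indexed by residue number (single chain)."""
    rows = {}
    for name in ("N", "CA", "C", "O", "H", "HN"):
        m = model.atom_name == name
        for res, xyz in zip(model.residue_number[m], model.coords[m]):
            rows.setdefault(int(res), {})["H" if name == "HN" else name] = xyz
    resnames = {}
    for res, rn in zip(model.residue_number, model.residue_name):
        resnames[int(res)] = str(rn)
    recs = []
    for res in sorted(rows):
        entry = rows[res]
        recs.append(
            {
                "residue": res,
                "residue_name": resnames.get(res, "UNK"),
                **{k: entry.get(k) for k in ("N", "CA", "C", "O", "H")},
            }
        )
    return pd.DataFrame(recs)


def _reconstruct_amide_h(bb: pd.DataFrame) -> None:
    """Place missing amide H 1.01 Å from N, opposite the C(prev)/CA bisector."""
    for k in range(1, len(bb)):
        if bb.at[k, "H"] is not None:
            continue
        if bb.at[k, "residue"] != bb.at[k - 1, "residue"] + 1:
            continue  # chain break: leave undefined
        n, ca, c_prev = bb.at[k, "N"], bb.at[k, "CA"], bb.at[k - 1, "C"]
        if n is None or ca is None or c_prev is None:
            continue
        d1 = n - c_prev
        d2 = n - ca
        d1 = d1 / np.linalg.norm(d1)
        d2 = d2 / np.linalg.norm(d2)
        direction = d1 + d2
        norm = np.linalg.norm(direction)
        if norm < 1e-8:
            continue
        bb.at[k, "H"] = n + 1.01 * direction / norm


def _hbond_matrix(bb: pd.DataFrame) -> np.ndarray:
    """hb[a, d] True when CO(acceptor a) accepts from NH(donor d)."""
    n = len(bb)
    residues = bb["residue"].to_numpy()
    hb = np.zeros((n, n), dtype=bool)
    ca = np.array(
        [c if c is not None else [np.nan] * 3 for c in bb["CA"]], dtype=float
    )
    for a in range(n):
        c_xyz, o_xyz = bb.at[a, "C"], bb.at[a, "O"]
        if c_xyz is None or o_xyz is None:
            continue
        for d in range(n):
            if abs(residues[d] - residues[a]) < 2:
                continue
            if bb.at[d, "residue_name"] == "PRO":
                continue
            n_xyz, h_xyz = bb.at[d, "N"], bb.at[d, "H"]
            if n_xyz is None or h_xyz is None:
                continue
            if np.linalg.norm(ca[a] - ca[d]) > 9.0:  # DSSP-style prefilter
                continue
            r_on = np.linalg.norm(o_xyz - n_xyz)
            r_ch = np.linalg.norm(c_xyz - h_xyz)
            r_oh = np.linalg.norm(o_xyz - h_xyz)
            r_cn = np.linalg.norm(c_xyz - n_xyz)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, not a physical bond
            energy = KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < HBOND_ENERGY_CUTOFF:
                hb[a, d] = True
    return hb


def assign_ss(model: Model) -> pd.Series:
    """Per-residue secondary structure label in {'H', 'E', 'C'}.

    Helix classes (3-10, alpha, pi) are merged into 'H'; isolated bridges
    and extended ladders are merged into 'E'.  Residues with missing
    backbone atoms are labelled 'C'.
    """
    bb = _backbone_by_residue(model)
    if bb.empty:
        raise ValueError("no backbone atoms found")
    missing = np.column_stack(
        [bb[c].map(lambda v: v is None).to_numpy() for c in ("N", "CA", "C", "O")]
    ).any(axis=1)
    if missing.any():
        _log.warning(
            "%d residues lack full backbone; labelled C", int(missing.sum())
        )
    _reconstruct_amide_h(bb)
    hb = _hbond_matrix(bb)
    n = len(bb)
    residues = bb["residue"].to_numpy()
    contiguous = np.zeros(n, dtype=bool)
    contiguous[:-1] = np.diff(residues) == 1

    labels = np.full(n, "C", dtype="<U1")

    # bridges / ladders -> E
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                labels[i] = "E"
                labels[j] = "E"

    # helical turns -> H (two consecutive i -> i+k turns required)
    def turn(i: int, k: int) -> bool:
        j = i + k
        if j >= n:
            return False
        if residues[j] - residues[i] != k:  # gap in numbering
            return False
        return bool(hb[i, j])

    for k, span in ((4, 4), (3, 3), (5, 5)):
        for i in range(1, n - k):
            if turn(i - 1, k) and turn(i, k):
                labels[i : i + span] = "H"

    return pd.Series(labels, index=residues, name="ss")


def ss_fractions(ensemble: Ensemble) -> dict[str, float]:
    """Ensemble-averaged secondary structure percentages; sums to 100."""
    counts = {"H": 0, "E": 0, "C": 0}
    total = 0
    for model in ensemble.models():
        ss = assign_ss(model)
        for label in ("H", "E", "C"):
            counts[label] += int((ss == label).sum())
        total += len(ss)
    fractions = {k: 100.0 * v / total for k, v in counts.items()}
    # force exact conservation against floating error
    fractions["C"] = 100.0 - fractions["H"] - fractions["E"]
    return fractions


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def dihedrals(model: Model) -> pd.DataFrame:
    """Backbone φ/ψ per residue (degrees); NaN at termini and chain breaks."""
    bb = _backbone_by_residue(model)
    res = bb["residue"].to_numpy()
    phi = np.full(len(bb), np.nan)
    psi = np.full(len(bb), np.nan)
    for k in range(len(bb)):
        n, ca, c = bb.at[k, "N"], bb.at[k, "CA"], bb.at[k, "C"]
        if any(v is None for v in (n, ca, c)):
            continue
        if k > 0 and res[k] - res[k - 1] == 1 and bb.at[k - 1, "C"] is not None:
            phi[k] = _dihedral(bb.at[k - 1, "C"], n, ca, c)
        if k < len(bb) - 1 and res[k + 1] - res[k] == 1 and bb.at[k + 1, "N"] is not None:
            psi[k] = _dihedral(n, ca, c, bb.at[k + 1, "N"])
    return pd.DataFrame({"residue": res, "phi": phi, "psi": psi})


def alpha_fraction(
    table: pd.DataFrame,
    residue_window: tuple[int, int],
    phi_window: tuple[float, float] = DEFAULT_ALPHA_PHI,
    psi_window: tuple[float, float] = DEFAULT_ALPHA_PSI,
) -> float:
    """Percentage of residues in ``residue_window`` with α-region φ/ψ."""
    first, last = residue_window
    sel = table[(table["residue"] >= first) & (table["residue"] <= last)]
    sel = sel.dropna(subset=["phi", "psi"])
    if sel.empty:
        raise ValueError("residue window contains no residues with defined φ/ψ")
    in_box = (
        (sel["phi"] >= phi_window[0])
        & (sel["phi"] <= phi_window[1])
        & (sel["psi"] >= psi_window[0])
        & (sel["psi"] <= psi_window[1])
    )
    return 100.0 * float(in_box.mean())


def ensemble_alpha_fraction(
    ensemble: Ensemble,
    residue_window: tuple[int, int],
    phi_window: tuple[float, float] = DEFAULT_ALPHA_PHI,
    psi_window: tuple[float, float] = DEFAULT_ALPHA_PSI,
) -> float:
    """α-region φ/ψ percentage averaged over ensemble members."""
    values = [
        alpha_fraction(dihedrals(m), residue_window, phi_window, psi_window)
        for m in ensemble.models()
    ]
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake–Rupley)
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(
    model: Model, probe_radius: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å^2) over heavy atoms.

    Hydrogens are ignored (united-atom convention); their entries are 0.
    """
    heavy = model.element != "H"
    coords = model.coords[heavy]
    elements = model.element[heavy]
    radii = np.empty(len(elements))
    for idx, el in enumerate(elements):
        if el not in VDW_RADII:
            _log.warning("unknown element %r; default radius used", el)
        radii[idx] = VDW_RADII.get(el, DEFAULT_VDW)
    radii = radii + probe_radius
    sphere = _sphere_points(n_points)
    n_heavy = len(coords)
    areas = np.zeros(n_heavy)
    for i in range(n_heavy):
        points = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        d_atoms = np.linalg.norm(coords - coords[i], axis=1)
        neighbours = np.flatnonzero((d_atoms < radii + radii[i]) & (d_atoms > 0))
        for j in neighbours:
            d = np.linalg.norm(points - coords[j], axis=1)
            accessible &= d >= radii[j]
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
    out = np.zeros(model.n_atoms)
    out[heavy] = areas
    return out


def sasa_ranking(
    model: Model, probe_radius: float = 1.4, n_points: int = 960
) -> pd.DataFrame:
    """Per-residue SASA, exposure relative to Gly-X-Gly reference, and rank.

    Rank 1 is the most exposed residue (descending relative exposure).
    """
    atom_sasa = shrake_rupley_sasa(model, probe_radius, n_points)
    df = pd.DataFrame(
        {
            "residue": model.residue_number,
            "residue_name": model.residue_name,
            "sasa": atom_sasa,
        }
    )
    per_res = (
        df.groupby(["residue", "residue_name"], sort=True)["sasa"].sum().reset_index()
    )
    ref = per_res["residue_name"].map(MAX_ASA)
    if ref.isna().any():
        _log.warning("unknown residue names in SASA reference; using ALA value")
        ref = ref.fillna(MAX_ASA["ALA"])
    per_res["rel_exposure"] = per_res["sasa"] / ref
    per_res["rank"] = (
        per_res["rel_exposure"].rank(ascending=False, method="first").astype(int)
    )
    return per_res.sort_values("rank").reset_index(drop=True)
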