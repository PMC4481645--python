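"""Restraint data model and bookkeeping for repeat-protein ensembles.

Covers sequence-separation categorisation of NOE distance restraints,
H-bond restraint generation from H/D-exchange protection, restraint
propagation across concatemer repeat units, radius-of-gyration restraint
specification, and violation statistics of coordinate ensembles against a
restraint set.  Structure calculation itself (simulated annealing) is out
of scope: restraints are generated, serialised and scored, never refined.

Category bounds follow the standard convention: intra-residue |i-j| = 0,
sequential = 1, medium-range 2-4, long-range >= 5; ambiguous restraints
are counted separately regardless of span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import Ensemble, get_logger

__all__ = [
    "DistanceRestraint",
    "DihedralRestraint",
    "HBondRestraint",
    "RgRestraintSpec",
    "RestraintSet",
    "ViolationReport",
    "categorize",
    "hbonds_from_hdx",
    "propagate",
    "score_violations",
    "make_rg_restraint",
    "rg_penalty",
    "read_restraints",
    "write_restraints",
]

_log = get_logger(__name__)

DEFAULT_HO_BOUNDS = (1.8, 2.3)  # Å
DEFAULT_NO_BOUNDS = (2.8, 3.3)  # Å


@dataclass(frozen=True)
class DistanceRestraint:
    """Distance bound between two atoms; ambiguous restraints carry several
    contributing pairs evaluated as an r^-6-summed effective distance."""

    pairs: tuple[tuple[int, str, int, str], ...]  # (res_i, atom_i, res_j, atom_j)
    lower: float
    upper: float

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("distance restraint needs at least one atom pair")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        for res_i, _, res_j, _ in self.pairs:
            if res_i < 1 or res_j < 1:
                raise ValueError("residue numbers must be >= 1")

    @property
    def ambiguous(self) -> bool:
        return len(self.pairs) > 1

    @classmethod
    def simple(cls, res_i, atom_i, res_j, atom_j, lower, upper):
        return cls(((int(res_i), atom_i, int(res_j), atom_j),), lower, upper)


@dataclass(frozen=True)
class DihedralRestraint:
    residue: int
    angle_name: str  # phi | psi
    target: float  # deg
    tolerance: float  # deg

    def __post_init__(self):
        if self.angle_name not in ("phi", "psi"):
            raise ValueError("angle_name must be 'phi' or 'psi'")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.residue < 1:
            raise ValueError("residue must be >= 1")


@dataclass(frozen=True)
class HBondRestraint:
    """Backbone amide H-bond: donor N-H of ``donor`` to carbonyl O of
    ``acceptor`` (acceptor = donor - 4 under the α-helix rule)."""

    donor: int
    acceptor: int
    ho_bounds: tuple[float, float] = DEFAULT_HO_BOUNDS
    no_bounds: tuple[float, float] = DEFAULT_NO_BOUNDS

    def __post_init__(self):
        if self.acceptor != self.donor - 4:
            raise ValueError("α-helical H-bond requires acceptor = donor - 4")

    def distance_restraints(self) -> list[DistanceRestraint]:
        return [
            DistanceRestraint.simple(self.donor, "H", self.acceptor, "O", *self.ho_bounds),
            DistanceRestraint.simple(self.donor, "N", self.acceptor, "O", *self.no_bounds),
        ]


@dataclass(frozen=True)
class RgRestraintSpec:
    """Serializable radius-of-gyration restraint for an annealing engine."""

    target_rg: float  # Å
    weight_scale: float = 1.0
    residue_selection: tuple[int, int] | None = None

    def __post_init__(self):
        if self.target_rg <= 0:
            raise ValueError("target Rg must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_rg_A": self.target_rg,
                "weight_scale": self.weight_scale,
                "residue_selection": self.residue_selection,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RgRestraintSpec":
        obj = json.loads(text)
        sel = obj.get("residue_selection")
        return cls(
            target_rg=obj["target_rg_A"],
            weight_scale=obj.get("weight_scale", 1.0),
            residue_selection=tuple(sel) if sel else None,
        )


@dataclass
class RestraintSet:
    distances: list[DistanceRestraint] = field(default_factory=list)
    dihedrals: list[DihedralRestraint] = field(default_factory=list)
    hbonds: list[HBondRestraint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.distances) + len(self.dihedrals) + len(self.hbonds)


@dataclass(frozen=True)
class ViolationReport:
    """Ensemble violation statistics, per-model then mean ± s.d."""

    distance_mean: float
    distance_sd: float
    distance_max_mean: float
    distance_max_sd: float
    dihedral_mean: float
    dihedral_sd: float
    dihedral_max_mean: float
    dihedral_max_sd: float
    n_distance: int
    n_dihedral: int
    n_unresolved: int = 0

    def as_dict(self) -> dict:
        return {
            "distance_constraints_A": [self.distance_mean, self.distance_sd],
            "max_distance_constraint_violation_A": [
                self.distance_max_mean,
                self.distance_max_sd,
            ],
            "dihedral_angle_constraints_deg": [self.dihedral_mean, self.dihedral_sd],
            "max_dihedral_angle_violation_deg": [
                self.dihedral_max_mean,
                self.dihedral_max_sd,
            ],
            "n_distance": self.n_distance,
            "n_dihedral": self.n_dihedral,
            "n_unresolved": self.n_unresolved,
        }


# ---------------------------------------------------------------------------
# Categorisation
# ---------------------------------------------------------------------------


def categorize(restraints: RestraintSet | list[DistanceRestraint]) -> dict[str, int]:
    """Count distance restraints by sequence separation.

    Returns counts for intra (|i-j| = 0), sequential (= 1), medium (2-4),
    long (>= 5) and ambiguous (multiple contributing pairs, counted apart).
    The categories partition the set: their sum equals the total.
    """
    distances = (
        restraints.distances if isinstance(restraints, RestraintSet) else restraints
    )
    counts = {"intra": 0, "sequential": 0, "medium": 0, "long": 0, "ambiguous": 0}
    for restraint in distances:
        if restraint.ambiguous:
            counts["ambiguous"] += 1
            continue
        res_i, _, res_j, _ = restraint.pairs[0]
        span = abs(res_i - res_j)
        if span == 0:
            counts["intra"] += 1
        elif span == 1:
            counts["sequential"] += 1
        elif span <= 4:
            counts["medium"] += 1
        else:
            counts["long"] += 1
    counts["total"] = sum(
        counts[k] for k in ("intra", "sequential", "medium", "long", "ambiguous")
    )
    return counts


# ---------------------------------------------------------------------------
# H/D exchange -> H-bond restraints
# ---------------------------------------------------------------------------


def hbonds_from_hdx(
    retained_residues,
    helix_segments,
    ho_bounds: tuple[float, float] = DEFAULT_HO_BOUNDS,
    no_bounds: tuple[float, float] = DEFAULT_NO_BOUNDS,
) -> list[HBondRestraint]:
    """α-helical H-bond restraints from exchange-protected amides.

    For each retained residue i lying inside a helix segment with
    i - 4 >= segment start, emit an H(i)···O(i-4) restraint; protected
    amides outside helices emit nothing (protection there is treated as
    unexplained rather than forced into a helical bond).
    """
    out = []
    for res in sorted(set(int(r) for r in retained_residues)):
        for start, end in helix_segments:
            if start <= res <= end and res - 4 >= start:
                out.append(
                    HBondRestraint(
                        donor=res,
                        acceptor=res - 4,
                        ho_bounds=ho_bounds,
                        no_bounds=no_bounds,
                    )
                )
                break
    return out


# ---------------------------------------------------------------------------
# Concatemer propagation
# ---------------------------------------------------------------------------


def propagate(
    restraints: RestraintSet, repeat_length: int = 200, n_units: int = 1
) -> RestraintSet:
    """Copy every restraint into each repeat unit of a concatemer.

    Unit u (1-based) shifts all residue numbers by (u-1)*repeat_length.
    No inter-unit restraints are created; |i-j| spans are preserved, so
    category counts scale exactly with ``n_units``.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    for restraint in restraints.distances:
        for res_i, _, res_j, _ in restraint.pairs:
            if max(res_i, res_j) > repeat_length:
                raise ValueError(
                    f"restraint residue {max(res_i, res_j)} exceeds repeat length"
                )
    for restraint in restraints.dihedrals:
        if restraint.residue > repeat_length:
            raise ValueError("dihedral restraint exceeds repeat length")
    for restraint in restraints.hbonds:
        if restraint.donor > repeat_length:
            raise ValueError("H-bond restraint exceeds repeat length")

    out = RestraintSet()
    for unit in range(n_units):
        shift = unit * repeat_length
        for restraint in restraints.distances:
            pairs = tuple(
                (ri + shift, ai, rj + shift, aj) for ri, ai, rj, aj in restraint.pairs
            )
            out.distances.append(
                DistanceRestraint(pairs, restraint.lower, restraint.upper)
            )
        for restraint in restraints.dihedrals:
            out.dihedrals.append(
                DihedralRestraint(
                    restraint.residue + shift,
                    restraint.angle_name,
                    restraint.target,
                    restraint.tolerance,
                )
            )
        for restraint in restraints.hbonds:
            out.hbonds.append(
                HBondRestraint(
                    restraint.donor + shift,
                    restraint.acceptor + shift,
                    restraint.ho_bounds,
                    restraint.no_bounds,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Violation scoring
# ---------------------------------------------------------------------------


def _effective_distance(model, pairs) -> float | None:
    """r^-6-summed effective distance over contributing pairs."""
    inv6 = 0.0
    resolved = False
    for res_i, atom_i, res_j, atom_j in pairs:
        a = model.atom_coord(res_i, atom_i)
        b = model.atom_coord(res_j, atom_j)
        if a is None or b is None:
            continue
        d = float(np.linalg.norm(a - b))
        if d <= 0:
            continue
        inv6 += d**-6
        resolved = True
    if not resolved:
        return None
    return inv6 ** (-1.0 / 6.0)


def _angle_violation(value: float, target: float, tolerance: float) -> float:
    diff = (value - target + 180.0) % 360.0 - 180.0
    return max(0.0, abs(diff) - tolerance)


def score_violations(ensemble: Ensemble, restraints: RestraintSet) -> ViolationReport:
    """Violation statistics of an ensemble against a restraint set.

    Distance violation is max(0, d - upper, lower - d) with the ambiguous
    r^-6 convention; H-bond restraints contribute their two distance
    bounds.  Dihedral violation is the angular excess beyond the stated
    tolerance.  Statistics are computed per model, then reported as the
    ensemble mean ± s.d. of the per-model mean and maximum.
    """
    from .metrics import dihedrals as _dihedrals  # local import, avoids cycle

    distance_restraints = list(restraints.distances)
    for hb in restraints.hbonds:
        distance_restraints.extend(hb.distance_restraints())

    per_model_mean, per_model_max = [], []
    per_model_dmean, per_model_dmax = [], []
    unresolved = 0
    any_resolved = False
    for model in ensemble.models():
        dviol = []
        for restraint in distance_restraints:
            d = _effective_distance(model, restraint.pairs)
            if d is None:
                unresolved += 1
                continue
            any_resolved = True
            dviol.append(max(0.0, d - restraint.upper, restraint.lower - d))
        aviol = []
        if restraints.dihedrals:
            table = _dihedrals(model).set_index("residue")
            for restraint in restraints.dihedrals:
                if restraint.residue not in table.index:
                    unresolved += 1
                    continue
                value = table.at[restraint.residue, restraint.angle_name]
                if np.isnan(value):
                    unresolved += 1
                    continue
                any_resolved = True
                aviol.append(
                    _angle_violation(value, restraint.target, restraint.tolerance)
                )
        per_model_mean.append(np.mean(dviol) if dviol else 0.0)
        per_model_max.append(np.max(dviol) if dviol else 0.0)
        per_model_dmean.append(np.mean(aviol) if aviol else 0.0)
        per_model_dmax.append(np.max(aviol) if aviol else 0.0)

    if distance_restraints or restraints.dihedrals:
        if not any_resolved:
            raise ValueError("no restrained atoms resolvable in the ensemble")
    if unresolved:
        _log.warning("%d restraint evaluations unresolved (missing atoms)", unresolved)

    def stats(values):
        arr = np.asarray(values, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=0))

    dm, ds = stats(per_model_mean)
    dxm, dxs = stats(per_model_max)
    am, asd = stats(per_model_dmean)
    axm, axs = stats(per_model_dmax)
    return ViolationReport(
        distance_mean=dm,
        distance_sd=ds,
        distance_max_mean=dxm,
        distance_max_sd=dxs,
        dihedral_mean=am,
        dihedral_sd=asd,
        dihedral_max_mean=axm,
        dihedral_max_sd=axs,
        n_distance=len(distance_restraints),
        n_dihedral=len(restraints.dihedrals),
        n_unresolved=unresolved,
    )


def make_rg_restraint(
    dosy_rg: float, weight_scale: float = 1.0, residue_selection=None
) -> RgRestraintSpec:
    """Radius-of-gyration restraint specification from a DOSY-derived Rg."""
    return RgRestraintSpec(
        target_rg=float(dosy_rg),
        weight_scale=float(weight_scale),
        residue_selection=tuple(residue_selection) if residue_selection else None,
    )


def rg_penalty(ensemble: Ensemble, spec: RgRestraintSpec) -> float:
    """Score-only harmonic Rg penalty, mean over models (Å^2 units).

    penalty = weight * (Rg_model - Rg_target)^2; no annealing is performed.
    """
    from .hydro import rg_from_coordinates

    penalties = []
    for model in ensemble.models():
        if spec.residue_selection is not None:
            mask = model.mask(residue_range=spec.residue_selection)
            coords = model.coords[mask]
        else:
            coords = model.coords
        rg = rg_from_coordinates(coords)
        penalties.append(spec.weight_scale * (rg - spec.target_rg) ** 2)
    return float(np.mean(penalties))


# ---------------------------------------------------------------------------
# Tabular text serialisation
# ---------------------------------------------------------------------------
#
# One restraint per line:
#   dist <group> <res_i> <atom_i> <res_j> <atom_j> <lower> <upper>
#       (lines sharing a group id > 0 form one ambiguous restraint)
#   dihe <residue> <phi|psi> <target> <tolerance>
#   hbnd <donor> <acceptor> <ho_lo> <ho_hi> <no_lo> <no_hi>


def write_restraints(restraints: RestraintSet, target) -> None:
    stream = target if hasattr(target, "write") else open(target, "w")
    try:
        group = 0
        for restraint in restraints.distances:
            group += 1
            gid = group if restraint.ambiguous else 0
            for res_i, atom_i, res_j, atom_j in restraint.pairs:
                stream.write(
                    f"dist {gid} {res_i} {atom_i} {res_j} {atom_j} "
                    f"{restraint.lower:g} {restraint.upper:g}\n"
                )
        for restraint in restraints.dihedrals:
            stream.write(
                f"dihe {restraint.residue} {restraint.angle_name} "
                f"{restraint.target:g} {restraint.tolerance:g}\n"
            )
        for restraint in restraints.hbonds:
            stream.write(
                f"hbnd {restraint.donor} {restraint.acceptor} "
                f"{restraint.ho_bounds[0]:g} {restraint.ho_bounds[1]:g} "
                f"{restraint.no_bounds[0]:g} {restraint.no_bounds[1]:g}\n"
            )
    finally:
        if stream is not target:
            stream.close()


def read_restraints(source) -> RestraintSet:
    stream = source if hasattr(source, "read") else open(source)
    try:
        out = RestraintSet()
        groups: dict[int, list] = {}
        group_bounds: dict[int, tuple[float, float]] = {}
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            kind = fields[0]
            try:
                if kind == "dist":
                    gid = int(fields[1])
                    res_i, atom_i = int(fields[2]), fields[3]
                    res_j, atom_j = int(fields[4]), fields[5]
                    lower, upper = float(fields[6]), float(fields[7])
                    if gid == 0:
                        out.distances.append(
                            DistanceRestraint.simple(
                                res_i, atom_i, res_j, atom_j, lower, upper
                            )
                        )
                    else:
                        groups.setdefault(gid, []).append(
                            (res_i, atom_i, res_j, atom_j)
                        )
                        group_bounds[gid] = (lower, upper)
                elif kind == "dihe":
                    out.dihedrals.append(
                        DihedralRestraint(
                            int(fields[1]), fields[2], float(fields[3]), float(fields[4])
                        )
                    )
                elif kind == "hbnd":
                    out.hbonds.append(
                        HBondRestraint(
                            int(fields[1]),
                            int(fields[2]),
                            (float(fields[3]), float(fields[4])),
                            (float(fields[5]), float(fields[6])),
                        )
                    )
                else:
                    raise ValueError(f"unknown record kind {kind!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
        for gid, pairs in groups.items():
            lower, upper = group_bounds[gid]
            out.distances.append(DistanceRestraint(tuple(pairs), lower, upper))
        return out
    finally:
        if stream is not source:
            stream.close()
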