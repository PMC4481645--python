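"""Chemical-shift perturbation (CSD) mapping and heteronuclear NOE analysis.

The combined chemical-shift displacement between two conditions is the
gyromagnetic-ratio-weighted Euclidean difference

    CSD = sqrt( sum_i (w_i * Δδ_i)^2 / n )

with w_H = 1, w_N = 0.102, w_C = 0.251 and n the number of nuclei compared
for that residue; the 1/n normalisation puts profiles with different
nucleus coverage (H/N-only titrations vs full-backbone modularity maps) on
one scale.  Steady-state heteronuclear 1H-15N NOE enhancement factors are
peak-height ratios I(sat)/I(ref); a plateau at or above ~0.65 marks a
rigidly tumbling core while low or negative values mark ps–ns flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ShiftTable, get_logger

__all__ = [
    "NUCLEUS_WEIGHTS",
    "ResidueMap",
    "CSDProfile",
    "HetNOEProfile",
    "csd",
    "normalize_csd",
    "perturbed_regions",
    "hetnoe",
    "order_segments",
]

_log = get_logger(__name__)

# weights from gyromagnetic ratios relative to 1H
NUCLEUS_WEIGHTS = {"H": 1.0, "N": 0.102, "CA": 0.251, "CO": 0.251, "C": 0.251}

HETNOE_ORDER_CUTOFF = 0.65


@dataclass(frozen=True)
class ResidueMap:
    """Injective residue-number map aligning condition A onto condition B.

    For comparing repeat unit u of an n-unit concatemer against the isolated
    unit, the map is a constant offset: residue i of the isolated unit maps
    to i + (u-1)*repeat_length in the concatemer.
    """

    pairs: dict[int, int]

    def __post_init__(self):
        values = list(self.pairs.values())
        if len(set(values)) != len(values):
            raise ValueError("residue map must be injective")

    @classmethod
    def offset(cls, residues, offset: int) -> "ResidueMap":
        return cls({int(r): int(r) + offset for r in residues})

    @classmethod
    def identity(cls, residues) -> "ResidueMap":
        return cls.offset(residues, 0)


@dataclass
class CSDProfile:
    """Per-residue combined chemical-shift displacement (ppm)."""

    data: pd.DataFrame  # columns: residue, csd, n_nuclei
    nuclei: tuple[str, ...]
    label: str = ""
    normalized: bool = False

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.data["csd"].to_numpy()


@dataclass
class HetNOEProfile:
    """Per-residue I(sat)/I(ref) enhancement factors."""

    data: pd.DataFrame  # columns: residue, noe [, flagged]
    cutoff: float = HETNOE_ORDER_CUTOFF

    def __post_init__(self):
        if not (-1.0 < self.cutoff <= 1.0):
            raise ValueError("cutoff must lie in (-1, 1]")
        if not np.all(np.isfinite(self.data["noe"].to_numpy(dtype=float))):
            raise ValueError("non-finite enhancement factor")

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.data["noe"].to_numpy()


def csd(
    shifts_a: ShiftTable,
    shifts_b: ShiftTable,
    residue_map: ResidueMap | None = None,
    nuclei: tuple[str, ...] = ("H", "N", "CA", "CO"),
    weights: dict[str, float] | None = None,
) -> CSDProfile:
    """Combined chemical-shift displacement of B relative to A, per residue.

    Residues present in only one table are omitted (flagged absent rather
    than scored zero).  ``residue_map`` maps A residue numbers to B residue
    numbers (identity by default); the output is indexed by A numbering.
    """
    weights = dict(NUCLEUS_WEIGHTS, **(weights or {}))
    if residue_map is None:
        residue_map = ResidueMap.identity(shifts_a.residues)
    rows = []
    for res_a, res_b in sorted(residue_map.pairs.items()):
        terms = []
        for nucleus in nuclei:
            sa = shifts_a.shifts(nucleus)
            sb = shifts_b.shifts(nucleus)
            if res_a in sa.index and res_b in sb.index:
                delta = sb.loc[res_b] - sa.loc[res_a]
                terms.append((weights[nucleus] * delta) ** 2)
        if not terms:
            continue
        rows.append(
            {
                "residue": res_a,
                "csd": float(np.sqrt(np.sum(terms) / len(terms))),
                "n_nuclei": len(terms),
            }
        )
    if not rows:
        raise ValueError("no residues shared between the two shift tables")
    label = f"{shifts_b.condition or 'B'} vs {shifts_a.condition or 'A'}"
    return CSDProfile(pd.DataFrame(rows), nuclei=tuple(nuclei), label=label)


def normalize_csd(profile: CSDProfile) -> CSDProfile:
    """Scale a CSD profile so its maximum equals 1."""
    peak = profile.values.max() if len(profile.values) else 0.0
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero CSD profile")
    data = profile.data.copy()
    data["csd"] = data["csd"] / peak
    return CSDProfile(data, nuclei=profile.nuclei, label=profile.label, normalized=True)


def perturbed_regions(
    profile: CSDProfile,
    threshold: float | None = None,
    n_sd: float = 1.0,
    gap_tolerance: int = 1,
) -> list[tuple[int, int]]:
    """Residue intervals where CSD exceeds a threshold (default mean + 1 s.d.).

    Intervals separated by gaps of at most ``gap_tolerance`` residues are
    merged.
    """
    values = profile.values
    residues = profile.residues
    if threshold is None:
        threshold = float(values.mean() + n_sd * values.std(ddof=0))
    hot = residues[values > threshold]
    if hot.size == 0:
        return []
    intervals = []
    start = prev = int(hot[0])
    for res in hot[1:]:
        res = int(res)
        if res - prev <= gap_tolerance + 1:
            prev = res
        else:
            intervals.append((start, prev))
            start = prev = res
    intervals.append((start, prev))
    return intervals


def hetnoe(
    sat_heights: pd.DataFrame,
    ref_heights: pd.DataFrame,
    cutoff: float = HETNOE_ORDER_CUTOFF,
) -> HetNOEProfile:
    """Enhancement factor I(sat)/I(ref) per residue.

    Inputs are DataFrames with columns ``residue`` and ``height``.  Residues
    with a zero reference height are flagged and excluded.
    """
    sat = sat_heights.set_index("residue")["height"]
    ref = ref_heights.set_index("residue")["height"]
    shared = sat.index.intersection(ref.index)
    if shared.empty:
        raise ValueError("no residues shared between saturated/reference tables")
    zero_ref = shared[ref.loc[shared] == 0]
    if len(zero_ref):
        _log.warning("excluding %d residues with zero reference height", len(zero_ref))
    keep = shared.difference(zero_ref)
    data = pd.DataFrame(
        {
            "residue": keep.to_numpy(dtype=int),
            "noe": (sat.loc[keep] / ref.loc[keep]).to_numpy(dtype=float),
        }
    ).sort_values("residue", ignore_index=True)
    return HetNOEProfile(data, cutoff=cutoff)


def order_segments(
    profile: HetNOEProfile, min_run: int = 3
) -> dict[str, list[tuple[int, int]]]:
    """Partition the covered residue range into ordered/disordered intervals.

    A residue is ordered when its enhancement factor is at or above the
    profile cutoff; runs shorter than ``min_run`` are absorbed into their
    neighbours (single-residue dips do not break an ordered stretch).
    """
    residues = profile.residues
    ordered = profile.values >= profile.cutoff
    # absorb short runs into the surrounding state
    runs: list[list] = []  # [state, start_idx, end_idx]
    for idx, state in enumerate(ordered):
        if runs and runs[-1][0] == state:
            runs[-1][2] = idx
        else:
            runs.append([bool(state), idx, idx])
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, run in enumerate(runs):
            length = run[2] - run[1] + 1
            if length < min_run and len(runs) > 1:
                neighbour = runs[k - 1] if k > 0 else runs[k + 1]
                run[0] = neighbour[0]
                # merge adjacent same-state runs
                merged: list[list] = []
                for r in runs:
                    if merged and merged[-1][0] == r[0]:
                        merged[-1][2] = r[2]
                    else:
                        merged.append(r)
                runs = merged
                changed = True
                break
    out: dict[str, list[tuple[int, int]]] = {"ordered": [], "disordered": []}
    for state, start, end in runs:
        key = "ordered" if state else "disordered"
        out[key].append((int(residues[start]), int(residues[end])))
    return out
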