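"""Readers/writers and in-memory containers shared by all analysis modules.

Conventions: residue numbering is 1-based as deposited, never renumbered;
distances are in Å and chemical shifts in ppm.  PDB parsing is backed by
biotite; tabular formats are plain CSV plus a minimal NMR-STAR-style loop
dialect for chemical shifts.
"""

from __future__ import annotations

import io as _io
import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure import stack as _stack_models
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Ensemble",
    "Model",
    "ShiftTable",
    "XYTable",
    "ParseError",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_shift_table",
    "write_shift_table",
    "read_xy_table",
    "write_xy_table",
    "load_config",
    "get_logger",
]

X_KINDS = {
    "gradient_percent",
    "gradient_G_per_cm",
    "wavenumber_cm-1",
    "concentration_M",
    "molar_ratio",
    "strain",
    "wavelength_nm",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ParseError(ValueError):
    """Raised when an input stream violates a format or container invariant."""


def get_logger(name: str = "wsilk") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


# ---------------------------------------------------------------------------
# Coordinate ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Model:
    """A single coordinate set sharing the parent ensemble's atom inventory."""

    coords: np.ndarray  # (n_atoms, 3) Å
    atom_name: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def mask(self, atom_names=None, residue_range=None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            m &= np.isin(self.atom_name, list(atom_names))
        if residue_range is not None:
            first, last = residue_range
            m &= (self.residue_number >= first) & (self.residue_number <= last)
        return m

    def atom_coord(self, residue_number: int, atom_name: str) -> np.ndarray | None:
        m = (self.residue_number == residue_number) & (self.atom_name == atom_name)
        idx = np.flatnonzero(m)
        if idx.size == 0:
            return None
        return self.coords[idx[0]]


@dataclass(frozen=True)
class Ensemble:
    """Multi-model atomic coordinate set with a shared atom inventory."""

    coords: np.ndarray  # (n_models, n_atoms, 3) Å
    atom_name: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray

    def __post_init__(self):
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ParseError("no atoms: ensemble needs >=1 model")
        if self.coords.shape[1] != len(self.atom_name):
            raise ParseError("ragged ensemble: coordinate/atom inventory mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ParseError("non-finite coordinates")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_range(self) -> tuple[int, int]:
        return int(self.residue_number.min()), int(self.residue_number.max())

    def model(self, i: int) -> Model:
        return Model(
            coords=self.coords[i],
            atom_name=self.atom_name,
            residue_number=self.residue_number,
            residue_name=self.residue_name,
            chain_id=self.chain_id,
            element=self.element,
        )

    def models(self):
        return [self.model(i) for i in range(self.n_models)]

    def subset(self, mask: np.ndarray) -> "Ensemble":
        return Ensemble(
            coords=self.coords[:, mask],
            atom_name=self.atom_name[mask],
            residue_number=self.residue_number[mask],
            residue_name=self.residue_name[mask],
            chain_id=self.chain_id[mask],
            element=self.element[mask],
        )


def _ensemble_from_stack(stack: AtomArrayStack) -> Ensemble:
    return Ensemble(
        coords=np.asarray(stack.coord, dtype=float),
        atom_name=np.asarray(stack.atom_name),
        residue_number=np.asarray(stack.res_id, dtype=int),
        residue_name=np.asarray(stack.res_name),
        chain_id=np.asarray(stack.chain_id),
        element=np.asarray(stack.element),
    )


def read_pdb_ensemble(source, keep_hetatm: bool = False) -> Ensemble:
    """Read a (possibly multi-MODEL) PDB file into an :class:`Ensemble`.

    ``source`` may be a path or an open text stream.  Files without MODEL
    records yield a single-model ensemble.  Models with inconsistent atom
    inventories raise ``ParseError("ragged ensemble")``; a file with no
    ATOM records raises ``ParseError("no atoms")``.
    """
    if hasattr(source, "read"):
        pdb = PDBFile.read(source)
    else:
        pdb = PDBFile.read(str(source))
    try:
        structure = pdb.get_structure()
    except Exception as exc:  # biotite raises on ragged model blocks
        raise ParseError(f"ragged ensemble: {exc}") from exc
    if isinstance(structure, AtomArray):  # single unlabelled model
        structure = _stack_models([structure])
    if structure.array_length() == 0:
        raise ParseError("no atoms")
    if not keep_hetatm:
        structure = structure[..., ~structure.hetero]
        if structure.array_length() == 0:
            raise ParseError("no atoms (only HETATM records present)")
    return _ensemble_from_stack(structure)


def write_pdb_ensemble(ensemble: Ensemble, target) -> None:
    """Write an ensemble as a multi-MODEL PDB file (path or text stream)."""
    stack = AtomArrayStack(ensemble.n_models, ensemble.n_atoms)
    stack.coord = np.asarray(ensemble.coords, dtype=np.float32)
    stack.atom_name = ensemble.atom_name
    stack.res_id = ensemble.residue_number
    stack.res_name = ensemble.residue_name
    stack.chain_id = ensemble.chain_id
    stack.element = ensemble.element
    stack.hetero = np.zeros(ensemble.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    if hasattr(target, "write"):
        pdb.write(target)
    else:
        pdb.write(str(target))


# ---------------------------------------------------------------------------
# Chemical shift tables
# ---------------------------------------------------------------------------


@dataclass
class ShiftTable:
    """Per-residue, per-nucleus chemical shifts (ppm) under one condition."""

    data: pd.DataFrame  # columns: residue, residue_name, nucleus, shift
    condition: str = ""

    def __post_init__(self):
        required = {"residue", "residue_name", "nucleus", "shift"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParseError(f"shift table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["residue", "nucleus"])
        if dup.any():
            rows = self.data.loc[dup, ["residue", "nucleus"]].to_records(index=False)
            raise ParseError(f"duplicate (residue, nucleus) entries: {list(rows)[:5]}")
        if not np.all(np.isfinite(self.data["shift"].to_numpy(dtype=float))):
            raise ParseError("non-finite chemical shift")
        self.data = self.data.astype({"residue": int, "shift": float}).reset_index(
            drop=True
        )

    def shifts(self, nucleus: str) -> pd.Series:
        sel = self.data[self.data["nucleus"] == nucleus]
        return sel.set_index("residue")["shift"]

    @property
    def residues(self) -> np.ndarray:
        return np.unique(self.data["residue"].to_numpy())


def read_shift_table(source, dialect: str = "csv", condition: str = "") -> ShiftTable:
    """Read a shift table from CSV or a minimal NMR-STAR-style loop.

    The CSV dialect expects the header ``residue,residue_name,nucleus,shift``.
    The ``star`` dialect accepts a ``loop_`` block whose ``_...`` tags include
    (in any order) ``Seq_ID``/``Comp_index_ID``, ``Comp_ID``, ``Atom_ID`` and
    ``Val``; other tags are ignored.
    """
    stream = source if hasattr(source, "read") else open(source)
    try:
        if dialect == "csv":
            df = _read_shift_csv(stream)
        elif dialect == "star":
            df = _read_shift_star(stream)
        else:
            raise ParseError(f"unknown shift-table dialect: {dialect!r}")
    finally:
        if stream is not source:
            stream.close()
    return ShiftTable(df, condition=condition)


def _read_shift_csv(stream) -> pd.DataFrame:
    df = pd.read_csv(stream)
    df.columns = [c.strip().lower() for c in df.columns]
    for lineno, value in enumerate(df.get("shift", pd.Series(dtype=object)), start=2):
        try:
            float(value)
        except (TypeError, ValueError):
            raise ParseError(f"line {lineno}: unparseable shift {value!r}") from None
    return df


_STAR_TAGS = {
    "seq_id": "residue",
    "comp_index_id": "residue",
    "comp_id": "residue_name",
    "atom_id": "nucleus",
    "val": "shift",
}


def _read_shift_star(stream) -> pd.DataFrame:
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "loop_":
            in_loop, tags, rows = True, [], []
            continue
        if not in_loop:
            continue
        if line.startswith("_"):
            tags.append(line.lstrip("_").split(".")[-1].lower())
            continue
        if line in ("stop_",):
            break
        values = line.split()
        if len(values) != len(tags):
            raise ParseError(f"line {lineno}: expected {len(tags)} fields")
        rows.append(values)
    if not tags:
        raise ParseError("no loop_ block found")
    df = pd.DataFrame(rows, columns=tags)
    renamed = df.rename(columns=_STAR_TAGS)
    missing = {"residue", "residue_name", "nucleus", "shift"} - set(renamed.columns)
    if missing:
        raise ParseError(f"star loop missing tags for: {sorted(missing)}")
    out = renamed[["residue", "residue_name", "nucleus", "shift"]].copy()
    try:
        out["residue"] = out["residue"].astype(int)
        out["shift"] = out["shift"].astype(float)
    except ValueError as exc:
        raise ParseError(f"unparseable star value: {exc}") from exc
    return out


def write_shift_table(table: ShiftTable, target) -> None:
    cols = ["residue", "residue_name", "nucleus", "shift"]
    if hasattr(target, "write"):
        table.data[cols].to_csv(target, index=False)
    else:
        table.data[cols].to_csv(str(target), index=False)


# ---------------------------------------------------------------------------
# Generic XY tables (decays, spectra, titrations, stress-strain)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class XYTable:
    """Ordered (x, y) series with a declared x-axis kind."""

    x: np.ndarray
    y: np.ndarray
    x_kind: str

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x_kind not in X_KINDS:
            raise ParseError(f"unknown x_kind {self.x_kind!r}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ParseError("x and y must be 1-D and equal length")
        if self.x.size and np.any(np.diff(self.x) <= 0):
            raise ParseError("x must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ParseError("non-finite values in XY table")

    def __len__(self) -> int:
        return self.x.size

    def with_y(self, y: np.ndarray) -> "XYTable":
        return XYTable(self.x.copy(), np.asarray(y, dtype=float), self.x_kind)


def read_xy_table(source, x_kind: str) -> XYTable:
    """Read a 2-column CSV (optional header) into an XYTable, sorted by x."""
    stream = source if hasattr(source, "read") else open(source)
    try:
        text = stream.read()
    finally:
        if stream is not source:
            stream.close()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    has_header = False
    if first:
        try:
            [float(v) for v in first.split(",")[:2]]
        except ValueError:
            has_header = True
    df = pd.read_csv(_io.StringIO(text), header=0 if has_header else None)
    if df.shape[1] < 2:
        raise ParseError("XY table needs two columns")
    try:
        x = df.iloc[:, 0].astype(float).to_numpy()
        y = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-numeric value in XY table: {exc}") from exc
    order = np.argsort(x, kind="stable")
    return XYTable(x[order], y[order], x_kind)


def write_xy_table(table: XYTable, target, labels=("x", "y")) -> None:
    df = pd.DataFrame({labels[0]: table.x, labels[1]: table.y})
    if hasattr(target, "write"):
        df.to_csv(target, index=False)
    else:
        df.to_csv(str(target), index=False)


def load_config(source) -> dict:
    """Load a YAML configuration mapping (path or stream)."""
    stream = source if hasattr(source, "read") else open(source)
    try:
        cfg = yaml.safe_load(stream)
    finally:
        if stream is not source:
            stream.close()
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParseError("config must be a mapping")
    return cfg
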