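"""Cavity-feature table I/O, [0,1] normalization, and structural extraction.

Each MD snapshot is described by four substrate-binding-cavity descriptors:
accessible surface area (A^2), cavity volume (A^3), heavy-atom count, and
backbone RMSD versus the first frame (A).  Area and volume are ingested as
precomputed columns (pocket-surface tools such as CASTp produce them); RMSD
and heavy-atom counts can optionally be computed in-repo from a multi-model
PDB trajectory given the cavity residue list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("area_A2", "volume_A3", "heavy_atoms", "rmsd_A")
TABLE_COLUMNS = ("snapshot_id", "time_ps") + FEATURE_COLUMNS
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class FeatureParseError(ValueError):
    """A cell could not be parsed as a number."""


class IntegrityError(ValueError):
    """A table invariant (uniqueness, ordering, sign) is violated."""


class StructureError(ValueError):
    """A cavity residue or backbone atom is missing from a model."""


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFeatureTable:
    """One row per MD snapshot with the four cavity descriptors.

    Invariants: unique snapshot ids, strictly increasing time, non-negative
    area/volume/RMSD, integer non-negative heavy-atom counts.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(TABLE_COLUMNS)].reset_index(drop=True)
        df["snapshot_id"] = df["snapshot_id"].astype(str)
        for col in ("time_ps", "area_A2", "volume_A3", "rmsd_A"):
            df[col] = df[col].astype(float)
        df["heavy_atoms"] = df["heavy_atoms"].astype(int)
        if df["snapshot_id"].duplicated().any():
            dup = df.loc[df["snapshot_id"].duplicated(), "snapshot_id"].iloc[0]
            raise IntegrityError(f"duplicate snapshot_id: {dup}")
        if len(df) > 1 and not (np.diff(df["time_ps"].to_numpy()) > 0).all():
            raise IntegrityError("time_ps must be strictly increasing")
        for col in ("area_A2", "volume_A3", "rmsd_A"):
            if (df[col] < 0).any():
                raise IntegrityError(f"negative value in column {col}")
        if (df["heavy_atoms"] < 0).any():
            raise IntegrityError("negative heavy-atom count")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def snapshot_ids(self) -> list[str]:
        return self.frame["snapshot_id"].tolist()

    def feature_matrix(self) -> np.ndarray:
        """The raw (n, 4) descriptor matrix in original units."""
        return self.frame.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)


def read_feature_table(path) -> TrajectoryFeatureTable:
    """Read a cavity-feature CSV (header ``snapshot_id,time_ps,area_A2,
    volume_A3,heavy_atoms,rmsd_A``), validating schema and invariants."""
    path = Path(path)
    raw = pd.read_csv(path, dtype={"snapshot_id": str})
    missing = [c for c in TABLE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
    for col in TABLE_COLUMNS[1:]:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, after the header line
            raise FeatureParseError(
                f"{path.name}: non-numeric value in column {col!r} at line {row}"
            )
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise FeatureParseError(f"{path.name}: empty cell in column {col!r} at line {row}")
        raw[col] = parsed
    return TrajectoryFeatureTable(raw)


def write_feature_table(table: TrajectoryFeatureTable, path) -> None:
    table.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedFeatureMatrix:
    """Min-max normalized (n, 4) feature matrix with the affine inverse.

    Every entry lies in [0, 1]; ``column_min``/``column_max`` retain the
    original units so the map can be inverted exactly.  A constant column
    normalizes to all zeros.
    """

    values: np.ndarray
    column_min: np.ndarray
    column_max: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise IntegrityError("normalized values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def inverse(self) -> np.ndarray:
        """Map back to original units: x = v * (max - min) + min."""
        span = self.column_max - self.column_min
        return self.values * span + self.column_min


def minmax_normalize(table) -> NormalizedFeatureMatrix:
    """Map each feature column onto [0, 1] by (x - min) / (max - min).

    Accepts a TrajectoryFeatureTable or a raw (n, d) array.  A constant
    column (max == min) maps to all zeros and logs a warning, so the feature
    count stays fixed even when e.g. the heavy-atom count never varies.
    """
    if isinstance(table, TrajectoryFeatureTable):
        X = table.feature_matrix()
        row_ids = table.snapshot_ids
        names = FEATURE_COLUMNS
    else:
        X = np.asarray(table, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        row_ids = [str(i) for i in range(X.shape[0])]
        names = tuple(f"col{i}" for i in range(X.shape[1]))
    if X.shape[0] == 0:
        raise IntegrityError("cannot normalize an empty table")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    constant = span == 0.0
    for name in np.asarray(names)[constant]:
        logger.warning("constant feature column %s normalized to all zeros", name)
    safe = np.where(constant, 1.0, span)
    values = (X - lo) / safe
    values[:, constant] = 0.0
    return NormalizedFeatureMatrix(values=values, column_min=lo, column_max=hi, row_ids=row_ids)


# ---------------------------------------------------------------------------
# structural extraction (optional path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CavitySpec:
    """The substrate-binding cavity as (chain id, author residue number)
    selectors, e.g. chain A of the pocket residues of a crystal reference."""

    residues: tuple

    def __post_init__(self) -> None:
        residues = tuple((str(c), int(r)) for c, r in self.residues)
        if not residues:
            raise ValueError("cavity residue list must be non-empty")
        if len(set(residues)) != len(residues):
            raise ValueError("duplicate cavity residue selector")
        object.__setattr__(self, "residues", residues)


def _load_structure(trajectory):
    if isinstance(trajectory, (str, Path)):
        from Bio.PDB import PDBParser

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return PDBParser(QUIET=True).get_structure("traj", str(trajectory))
    return trajectory


def _residue(model, chain_id: str, resnum: int):
    try:
        chain = model[chain_id]
        return chain[(" ", resnum, " ")]
    except KeyError:
        raise StructureError(f"cavity residue {chain_id}:{resnum} absent from model")


def _backbone_coords(model, cavity: CavitySpec) -> np.ndarray:
    coords = []
    for chain_id, resnum in cavity.residues:
        res = _residue(model, chain_id, resnum)
        for name in BACKBONE_ATOMS:
            if name not in res:
                raise StructureError(
                    f"missing backbone atom {name} in residue {chain_id}:{resnum}"
                )
            coords.append(res[name].coord)
    return np.asarray(coords, dtype=float)


def compute_cavity_rmsd(trajectory, cavity: CavitySpec, superpose: bool = True) -> np.ndarray:
    """Backbone (N, CA, C, O) RMSD of each model against model 1 over the
    cavity residues.

    With ``superpose=True`` (default) an optimal least-squares rigid
    superposition removes global rotation/translation before the deviation
    is measured, the convention of standard trajectory RMSD tools.  The
    first value is exactly 0.
    """
    structure = _load_structure(trajectory)
    models = list(structure)
    if not models:
        raise StructureError("trajectory contains no models")
    ref = _backbone_coords(models[0], cavity)
    out = np.empty(len(models))
    if superpose:
        from Bio.SVDSuperimposer import SVDSuperimposer

        sup = SVDSuperimposer()
    for i, model in enumerate(models):
        mob = _backbone_coords(model, cavity)
        if superpose:
            sup.set(ref, mob)
            sup.run()
            out[i] = float(sup.get_rms())
        else:
            out[i] = float(np.sqrt(((mob - ref) ** 2).sum(axis=1).mean()))
    out[0] = 0.0
    return out


def count_cavity_heavy_atoms(model, cavity: CavitySpec) -> int:
    """Number of non-hydrogen atoms in the cavity residues of one model."""
    count = 0
    for chain_id, resnum in cavity.residues:
        res = _residue(model, chain_id, resnum)
        for atom in res:
            element = (atom.element or "").strip().upper()
            if element not in ("H", "D"):
                count += 1
    return count
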