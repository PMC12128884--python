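"""Reflection-table I/O and Miller-index geometry.

A *study* is a directory holding one ``study.json`` metadata file and one
TSV reflection table per crystal.  Each table carries the scaled, unmerged
observations of one data set: Miller index ``(h, k, l)``, scaled intensity
``I`` and its uncertainty ``sigma``.  Symmetry is supplied explicitly as a
list of 3x3 integer rotation matrices acting on Miller indices; a space-group
symbol, when present, is carried through as documentation only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReflectionTable",
    "CrystalMetadata",
    "StudyFormatError",
    "read_study",
    "write_study",
    "d_spacing",
    "map_to_asu",
]

_TSV_COLUMNS = ["h", "k", "l", "intensity", "sigma"]


class StudyFormatError(ValueError):
    """Raised when a study directory or one of its files is malformed."""


@dataclass
class ReflectionTable:
    """Unmerged scaled observations of a single crystal.

    Parameters
    ----------
    dataset_id : str
        Identifier, by convention the TSV filename stem.
    hkl : (n, 3) int array
        Miller indices; no row may be (0, 0, 0).
    intensity : (n,) float array
        Scaled intensities (arbitrary common scale across the study).
    sigma : (n,) float array
        Uncertainties of the scaled intensities; strictly positive.
    """

    dataset_id: str
    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        n = len(self.hkl)
        if n == 0:
            raise StudyFormatError(
                f"dataset {self.dataset_id!r}: reflection table is empty"
            )
        if len(self.intensity) != n or len(self.sigma) != n:
            raise StudyFormatError(
                f"dataset {self.dataset_id!r}: column lengths differ"
            )
        if np.any(~np.isfinite(self.intensity)) or np.any(~np.isfinite(self.sigma)):
            raise StudyFormatError(
                f"dataset {self.dataset_id!r}: non-finite intensity or sigma"
            )
        if np.any(self.sigma <= 0):
            bad = int(np.flatnonzero(self.sigma <= 0)[0])
            raise StudyFormatError(
                f"dataset {self.dataset_id!r}: sigma must be > 0 "
                f"(row {bad} has sigma={self.sigma[bad]})"
            )
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise StudyFormatError(
                f"dataset {self.dataset_id!r}: Miller index (0,0,0) not allowed"
            )

    def __len__(self) -> int:
        return len(self.hkl)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": self.hkl[:, 0],
                "k": self.hkl[:, 1],
                "l": self.hkl[:, 2],
                "intensity": self.intensity,
                "sigma": self.sigma,
            }
        )


@dataclass
class CrystalMetadata:
    """Unit cell and symmetry shared by all data sets of a study.

    ``symmetry_ops`` are integer rotation parts R of the space-group
    operations; they act on a Miller index h as ``R^T h``.  Only
    unimodularity (det = +-1) is validated.  ``anomalous_flag`` decides
    whether Friedel mates (h and -h) are kept separate.
    """

    unit_cell: tuple[float, float, float, float, float, float]
    symmetry_ops: list[np.ndarray] = field(
        default_factory=lambda: [np.eye(3, dtype=np.int64)]
    )
    space_group_name: str | None = None
    anomalous_flag: bool = False

    def __post_init__(self) -> None:
        cell = tuple(float(v) for v in self.unit_cell)
        if len(cell) != 6:
            raise StudyFormatError("unit_cell must have six values (a,b,c,al,be,ga)")
        a, b, c, al, be, ga = cell
        if min(a, b, c) <= 0:
            raise StudyFormatError("unit_cell lengths must be positive")
        if not all(0 < ang < 180 for ang in (al, be, ga)):
            raise StudyFormatError("unit_cell angles must lie in (0, 180) degrees")
        self.unit_cell = cell
        ops = [np.asarray(op, dtype=np.int64).reshape(3, 3) for op in self.symmetry_ops]
        if not ops:
            raise StudyFormatError("symmetry_ops must be non-empty")
        for op in ops:
            det = int(round(np.linalg.det(op)))
            if det not in (1, -1):
                raise StudyFormatError(
                    f"symmetry op {op.tolist()} is not unimodular (det={det})"
                )
        self.symmetry_ops = ops


def d_spacing(hkl, cell) -> np.ndarray | float:
    """Resolution d (in angstrom) of Miller indices in a triclinic cell.

    Evaluates d = 1/|h A*| through the reciprocal metric tensor of the
    general (triclinic) cell, so any crystal system is covered.  Accepts a
    single index triple or an (n, 3) array.

    Raises
    ------
    ValueError
        If any index is (0, 0, 0).
    """
    h = np.asarray(hkl, dtype=float)
    single = h.ndim == 1
    h = h.reshape(-1, 3)
    if np.any(np.all(h == 0, axis=1)):
        raise ValueError("d-spacing undefined for Miller index (0,0,0)")
    g_star = _reciprocal_metric_tensor(cell)
    inv_d2 = np.einsum("ni,ij,nj->n", h, g_star, h)
    d = 1.0 / np.sqrt(inv_d2)
    return float(d[0]) if single else d


def _reciprocal_metric_tensor(cell) -> np.ndarray:
    a, b, c, al, be, ga = (float(v) for v in cell)
    al, be, ga = np.radians([al, be, ga])
    ca, cb, cg = np.cos([al, be, ga])
    # direct metric tensor, then invert: G* = G^-1
    g = np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )
    return np.linalg.inv(g)


def map_to_asu(table: ReflectionTable, meta: CrystalMetadata) -> ReflectionTable:
    """Replace each Miller index by its canonical symmetry-unique representative.

    The orbit of h is {R^T h for every rotation R}, extended by the Friedel
    mates {-R^T h} unless ``anomalous_flag`` is set.  The canonical
    representative is the lexicographically greatest (h, k, l) triple of the
    orbit; any consistent convention gives identical downstream merging.
    Idempotent, and intensities/sigmas are untouched.
    """
    candidates = []
    for op in meta.symmetry_ops:
        t = table.hkl @ op  # row-vector h times R == R^T h as column
        candidates.append(t)
        if not meta.anomalous_flag:
            candidates.append(-t)
    best = candidates[0]
    for cand in candidates[1:]:
        best = _lex_max(best, cand)
    return ReflectionTable(
        dataset_id=table.dataset_id,
        hkl=best,
        intensity=table.intensity.copy(),
        sigma=table.sigma.copy(),
    )


def _lex_max(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise lexicographic maximum of two (n, 3) integer arrays."""
    gt = (b[:, 0] > a[:, 0]) | (
        (b[:, 0] == a[:, 0])
        & ((b[:, 1] > a[:, 1]) | ((b[:, 1] == a[:, 1]) & (b[:, 2] > a[:, 2])))
    )
    return np.where(gt[:, None], b, a)


def read_study(path) -> tuple[list[ReflectionTable], CrystalMetadata]:
    """Read a study directory (study.json + one TSV per data set).

    Tables are returned in lexicographic order of their filenames; each
    ``dataset_id`` is the filename stem.
    """
    path = Path(path)
    meta_path = path / "study.json"
    if not meta_path.is_file():
        raise StudyFormatError(f"missing metadata file {meta_path}")
    try:
        raw = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise StudyFormatError(f"study.json is not valid JSON: {exc}") from exc
    for key in ("unit_cell", "symmetry_ops", "datasets"):
        if key not in raw:
            raise StudyFormatError(f"study.json missing required field {key!r}")
    meta = CrystalMetadata(
        unit_cell=tuple(raw["unit_cell"]),
        symmetry_ops=[np.asarray(op) for op in raw["symmetry_ops"]],
        space_group_name=raw.get("space_group_name"),
        anomalous_flag=bool(raw.get("anomalous", False)),
    )
    filenames = sorted(raw["datasets"])
    if len(filenames) < 2:
        raise StudyFormatError("a study needs at least 2 dataset files")
    tables = []
    for name in filenames:
        fpath = path / name
        if not fpath.is_file():
            raise StudyFormatError(f"dataset file {name!r} listed but not found")
        tables.append(_read_tsv(fpath))
    return tables, meta


def _read_tsv(fpath: Path) -> ReflectionTable:
    df = pd.read_csv(fpath, sep="\t")
    if list(df.columns) != _TSV_COLUMNS:
        raise StudyFormatError(
            f"dataset {fpath.stem!r}: header must be {_TSV_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    return ReflectionTable(
        dataset_id=fpath.stem,
        hkl=df[["h", "k", "l"]].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        sigma=df["sigma"].to_numpy(),
    )


def write_study(path, tables: list[ReflectionTable], meta: CrystalMetadata) -> None:
    """Write tables + metadata in the native study format (inverse of read_study)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    filenames = []
    for table in tables:
        name = f"{table.dataset_id}.tsv"
        table.to_frame().to_csv(path / name, sep="\t", index=False)
        filenames.append(name)
    meta_doc = {
        "unit_cell": list(meta.unit_cell),
        "symmetry_ops": [op.tolist() for op in meta.symmetry_ops],
        "space_group_name": meta.space_group_name,
        "anomalous": meta.anomalous_flag,
        "datasets": filenames,
    }
    (path / "study.json").write_text(json.dumps(meta_doc, indent=1))
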