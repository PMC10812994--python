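"""Shared spatial types and readers/writers for the formats the pipeline touches.

Volumes are NIfTI-1 (plain or gzipped), tables are TSV, gene sets are GMT.
Voxel indices are 0-based; world coordinates are millimetres in the volume
affine's frame (MNI-like for synthetic data). All reported peak coordinates
are world mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("neurotx")

#: column order for design tables; fixed so outputs are reproducible byte-wise
DESIGN_COLUMNS = ("subject_id", "group", "age", "sex", "education", "bmi")
GROUP_LEVELS = ("case", "control")
SEX_LEVELS = ("male", "female")


def configure_logging(verbosity: int = 1) -> None:
    """Configure the package logger. 0 = warnings, 1 = info, 2 = debug."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("[%(name)s %(levelname)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def log_stage(stage: str, **counts) -> None:
    """One structured line per pipeline stage: name plus input shapes/counts."""
    parts = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", stage, parts)


class FormatError(ValueError):
    """Malformed input file (header, schema, or dialect violation)."""


# ---------------------------------------------------------------------------
# Spatial types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGrid:
    """A 3D sampling grid: shape in voxels plus a 4x4 voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass(frozen=True)
class BinaryMask:
    grid: VolumeGrid
    inside: np.ndarray

    def __post_init__(self):
        inside = np.asarray(self.inside, dtype=bool)
        if inside.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not inside.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "inside", inside)

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of in-mask voxels, C order."""
        return np.argwhere(self.inside)

    def world_coordinates(self) -> np.ndarray:
        return self.grid.voxel_to_world(self.voxel_indices())


@dataclass
class TimeSeriesImage:
    """4D BOLD-like volume with repetition time and an analysis mask."""

    grid: VolumeGrid
    data: np.ndarray
    tr_seconds: float
    mask: BinaryMask

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("time series data must be 4D")
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError("data shape does not match grid")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(self.data[self.mask.inside]).all():
            raise ValueError("non-finite values inside mask")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def in_mask_series(self) -> np.ndarray:
        """(n_voxels, t) view of the in-mask time series."""
        return self.data[self.mask.inside]


@dataclass
class StatMap:
    """3D map of voxel statistics (t-values); the imaging/transcriptomics bridge."""

    grid: VolumeGrid
    values: np.ndarray
    dof: int
    mask: BinaryMask
    tail: str = "two_sided"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        if self.tail not in ("two_sided", "positive", "negative"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if not np.isfinite(self.values[self.mask.inside]).all():
            raise ValueError("non-finite statistic inside mask")
        # outside-mask voxels are undefined; flag them explicitly
        out = ~self.mask.inside
        self.values = self.values.copy()
        self.values[out] = np.nan

    def in_mask_values(self) -> np.ndarray:
        return self.values[self.mask.inside]


@dataclass(frozen=True)
class SubjectDesign:
    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    bmi: float

    def __post_init__(self):
        if self.group not in GROUP_LEVELS:
            raise ValueError(f"group must be one of {GROUP_LEVELS}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}")
        for name in ("age", "education", "bmi"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def read_volume(path, mask: BinaryMask | None = None,
                tr_seconds: float | None = None):
    """Read a NIfTI volume.

    4D files come back as :class:`TimeSeriesImage` (TR from the header's
    fourth zoom unless overridden); 3D files come back as a bare
    ``(VolumeGrid, ndarray)`` pair. A mask is required for 4D input; if
    omitted, the set of finite & nonzero-variance voxels would be ambiguous,
    so we refuse rather than guess.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float32)
        affine = img.affine
    except Exception as exc:  # nibabel raises several types for bad headers
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    grid = VolumeGrid(data.shape[:3], affine)
    if data.ndim == 4:
        if mask is None:
            raise ValueError("a mask is required to read a 4D volume")
        if tr_seconds is None:
            tr_seconds = float(img.header.get_zooms()[3])
        return TimeSeriesImage(grid, data, tr_seconds, mask)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D or 4D volume, got ndim={data.ndim}")
    if mask is not None and not np.isfinite(data[mask.inside]).all():
        logger.warning("non-finite voxels inside mask in %s", path)
    return grid, data


def write_volume(path, grid: VolumeGrid, data: np.ndarray,
                 tr_seconds: float | None = None) -> None:
    data = np.asarray(data, dtype=np.float32)
    img = nib.Nifti1Image(data, grid.affine)
    if data.ndim == 4 and tr_seconds is not None:
        zooms = tuple(grid.voxel_size) + (float(tr_seconds),)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    grid, data = read_volume(path)
    return BinaryMask(grid, data > 0.5)


def write_mask(path, mask: BinaryMask) -> None:
    write_volume(path, mask.grid, mask.inside.astype(np.float32))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_design_table(path) -> list[SubjectDesign]:
    """Read the subject covariate TSV (one row per subject)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"duplicated subject_id values: {dups}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(SubjectDesign(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                bmi=float(row["bmi"]),
            ))
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"bad design row for subject {row['subject_id']!r}: {exc}"
            ) from exc
    return records


def write_design_table(path, designs: Sequence[SubjectDesign]) -> None:
    df = pd.DataFrame([{c: getattr(d, c) for c in DESIGN_COLUMNS}
                       for d in designs], columns=list(DESIGN_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def format_float(x: float) -> str:
    """Serialize a float with 6 significant digits (fixed table convention)."""
    if isinstance(x, float) and not np.isfinite(x):
        return "nan"
    return f"{x:.6g}"


def write_table(path, df: pd.DataFrame) -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(format_float)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line: name <tab> description <tab> members.

    Member symbols are uppercased and deduplicated; empty sets and duplicate
    set names are rejected.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description, "
                    f"and at least one member"
                )
            name = parts[0]
            members = {m.strip().upper() for m in parts[2:] if m.strip()}
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gene_sets(path, sets: Mapping[str, Sequence[str]],
                    descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            members = sorted({str(m).upper() for m in sets[name]})
            fh.write("\t".join([name, desc, *members]) + "\n")
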